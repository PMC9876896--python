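"""Profile build-and-search backends.

Two interchangeable implementations of one contract — build a profile
from seed sequences, then search it against a protein dataset and return
per-domain hits:

``hmmer``
    Profile HMMs through pyhmmer (in-process HMMER3): the seed MSA is
    built with the package's center-star aligner, the profile with the
    standard hmmbuild procedure, and the search with the full HMMER
    pipeline, whose per-domain table is ingested via :mod:`.hmmerio`.

``builtin``
    A self-contained position-specific scoring matrix with empirical
    E-values. It aligns seeds (center-star), drops columns with more
    than 50% gaps, converts column frequencies to log-odds against a
    uniform background, scores every window of each target, and converts
    scores to E-values against a null of per-sequence maxima over
    residue-shuffled copies. It assumes one domain per target (best
    window only) and exists so the whole enrichment loop runs
    deterministically with no profile-HMM machinery; it is not a HMMER
    replacement.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .align import center_star_msa
from .errors import BackendUnavailableError, FormatError, UsageError
from .hmmerio import DomainHit, quantize_evalue, read_domtblout
from .seqio import SequenceRecord

__all__ = [
    "ProfileModel",
    "SearchParams",
    "build_profile",
    "search_profile",
    "empirical_evalue",
    "get_backend",
    "BuiltinBackend",
    "HmmerBackend",
]

#: Column order of the 20-letter alphabet used by the builtin matrices.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Pseudocount and background of the builtin model: column frequency
#: f = (count + 0.1) / (depth + 2.0), log-odds in bits against 1/20.
PSEUDOCOUNT = 0.1
PSEUDOCOUNT_TOTAL = 2.0
BACKGROUND = 1.0 / 20.0


@dataclass(frozen=True)
class SearchParams:
    """Search-time thresholds and null-model size."""

    evalue_max: float = 0.01
    acc_min: float = 0.6
    null_shuffles: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.null_shuffles < 1:
            raise ValueError("null_shuffles must be positive")


@dataclass(frozen=True)
class ProfileModel:
    """A built domain profile.

    ``kind`` is ``"external-file"`` (payload: path of a HMMER3 ASCII
    profile) or ``"builtin-pssm"`` (payload: log-odds matrix, columns x
    alphabet, in bits, plus the seed-MSA depth).
    """

    name: str
    length: int
    kind: Literal["external-file", "builtin-pssm"]
    path: Path | None = None
    matrix: np.ndarray | None = field(default=None, repr=False)
    msa_depth: int = 0
    msa_rows: tuple[str, ...] = field(default=(), repr=False)
    msa_ids: tuple[str, ...] = field(default=(), repr=False)

    def save(self, path: str | Path) -> Path:
        """Serialize the profile to ``path``.

        External profiles are copied byte-wise; builtin matrices are
        written in a named text block (NAME line, one row per column,
        ``//`` terminator) compatible with database concatenation.
        """
        path = Path(path)
        if self.kind == "external-file":
            assert self.path is not None
            path.write_bytes(Path(self.path).read_bytes())
            return path
        assert self.matrix is not None
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("ARCHMINER-PSSM [1.0]\n")
            fh.write(f"NAME  {self.name}\n")
            fh.write(f"LENG  {self.length}\n")
            fh.write(f"DEPTH {self.msa_depth}\n")
            fh.write("COLS  " + " ".join(ALPHABET) + "\n")
            for row in self.matrix:
                fh.write("  " + " ".join(f"{v:.5f}" for v in row) + "\n")
            fh.write("//\n")
        return path


def _load_builtin_profile(path: str | Path) -> ProfileModel:
    path = Path(path)
    name = None
    length = None
    depth = 0
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("NAME"):
                name = line.split()[1]
            elif line.startswith("LENG"):
                length = int(line.split()[1])
            elif line.startswith("DEPTH"):
                depth = int(line.split()[1])
            elif line.startswith("  "):
                rows.append([float(x) for x in line.split()])
    if name is None or length is None or len(rows) != length:
        raise FormatError(f"{path}: malformed builtin profile")
    return ProfileModel(
        name=name,
        length=length,
        kind="builtin-pssm",
        matrix=np.asarray(rows, dtype=float),
        msa_depth=depth,
    )


def empirical_evalue(
    score: float,
    profile: ProfileModel,
    dataset_size: int,
    null_scores: Sequence[float] | np.ndarray,
) -> float:
    """Empirical E-value of a window score against a shuffled null.

    E = dataset_size * (1 + #{null >= score}) / (1 + #null). The +1
    terms keep the estimate strictly positive and bounded by the dataset
    size; the function is non-increasing in the score.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise UsageError("empirical_evalue needs a non-empty null distribution")
    exceed = int(np.count_nonzero(null >= score))
    return dataset_size * (1 + exceed) / (1 + null.size)


class BuiltinBackend:
    """Position-specific scoring backend with empirical E-values."""

    name = "builtin"

    def build(self, seeds: Sequence[SequenceRecord], name: str) -> ProfileModel:
        if not seeds:
            raise UsageError("build_profile needs at least one seed sequence")
        rows = center_star_msa([s.residues for s in seeds])
        depth = len(rows)
        width = len(rows[0])
        keep = [
            c
            for c in range(width)
            if sum(r[c] == "-" for r in rows) <= depth / 2.0
        ]
        matrix = np.empty((len(keep), 20), dtype=float)
        for out_c, c in enumerate(keep):
            counts = np.zeros(20)
            for r in rows:
                idx = _AA_INDEX.get(r[c])
                if idx is not None:
                    counts[idx] += 1
            freqs = (counts + PSEUDOCOUNT) / (depth + PSEUDOCOUNT_TOTAL)
            matrix[out_c] = np.log2(freqs / BACKGROUND)
        return ProfileModel(
            name=name,
            length=len(keep),
            kind="builtin-pssm",
            matrix=matrix,
            msa_depth=depth,
            msa_rows=tuple(rows),
            msa_ids=tuple(s.id for s in seeds),
        )

    # -- scoring ---------------------------------------------------------

    @staticmethod
    def _encode(residues: str) -> np.ndarray:
        # letters outside the 20-letter alphabet map to a sentinel column
        # that scores 0 (neither evidence for nor against the profile)
        return np.fromiter(
            (_AA_INDEX.get(c, 20) for c in residues), dtype=np.int64, count=len(residues)
        )

    @staticmethod
    def _window_scores(matrix_ext: np.ndarray, codes: np.ndarray, L: int) -> np.ndarray:
        """Scores of all length-L windows of one encoded sequence."""
        n = codes.size
        nw = n - L + 1
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        return matrix_ext[np.arange(L)[None, :], windows].sum(axis=1)

    def _null_scores(
        self,
        matrix_ext: np.ndarray,
        encoded: list[np.ndarray],
        L: int,
        params: SearchParams,
    ) -> np.ndarray:
        rng = np.random.default_rng(params.rng_seed)
        out: list[np.ndarray] = []
        for codes in encoded:
            if codes.size < L:
                continue
            shuffled = rng.permuted(
                np.tile(codes, (params.null_shuffles, 1)), axis=1
            )
            windows = np.lib.stride_tricks.sliding_window_view(shuffled, L, axis=1)
            scores = matrix_ext[np.arange(L)[None, None, :], windows].sum(axis=2)
            out.append(scores.max(axis=1))
        if not out:
            return np.empty(0)
        return np.concatenate(out)

    def search(
        self,
        profile: ProfileModel,
        dataset: Sequence[SequenceRecord],
        params: SearchParams,
    ) -> list[DomainHit]:
        if profile.kind != "builtin-pssm" or profile.matrix is None:
            raise UsageError("builtin backend can only search builtin-pssm profiles")
        if not dataset:
            raise UsageError("search_profile needs a non-empty dataset")
        L = profile.length
        matrix_ext = np.hstack([profile.matrix, np.zeros((L, 1))])
        encoded = [self._encode(rec.residues) for rec in dataset]
        null = self._null_scores(matrix_ext, encoded, L, params)
        if null.size == 0:
            return []  # every sequence shorter than the profile
        hits: list[DomainHit] = []
        for rec, codes in zip(dataset, encoded):
            if codes.size < L:
                continue
            scores = self._window_scores(matrix_ext, codes, L)
            w = int(np.argmax(scores))
            # report at domtblout precision so written tables round-trip
            best = round(float(scores[w]), 1)
            evalue = quantize_evalue(
                empirical_evalue(float(scores[w]), profile, len(dataset), null)
            )
            window_codes = codes[w : w + L]
            positive = matrix_ext[np.arange(L), window_codes] > 0
            acc = round(float(np.count_nonzero(positive)) / L, 2)
            if evalue < params.evalue_max and acc >= params.acc_min:
                hits.append(
                    DomainHit(
                        target_id=rec.id,
                        target_len=len(rec.residues),
                        query_name=profile.name,
                        query_len=L,
                        full_evalue=evalue,
                        bitscore=best,
                        c_evalue=evalue,
                        i_evalue=evalue,
                        hmm_from=1,
                        hmm_to=L,
                        ali_from=w + 1,
                        ali_to=w + L,
                        env_from=w + 1,
                        env_to=w + L,
                        acc=acc,
                    )
                )
        return hits


class HmmerBackend:
    """Profile-HMM backend on top of pyhmmer (in-process HMMER3)."""

    name = "hmmer"

    def __init__(self) -> None:
        try:
            import pyhmmer  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise BackendUnavailableError(
                "the hmmer backend requires the pyhmmer package"
            ) from exc
        self._pyhmmer = pyhmmer

    def build(self, seeds: Sequence[SequenceRecord], name: str) -> ProfileModel:
        if not seeds:
            raise UsageError("build_profile needs at least one seed sequence")
        pyhmmer = self._pyhmmer
        abc = pyhmmer.easel.Alphabet.amino()
        builder = pyhmmer.plan7.Builder(abc)
        background = pyhmmer.plan7.Background(abc)
        if len(seeds) == 1:
            seq = pyhmmer.easel.TextSequence(
                name=name.encode(), sequence=seeds[0].residues.replace("*", "X")
            ).digitize(abc)
            hmm, _, _ = builder.build(seq, background)
            rows = (seeds[0].residues,)
        else:
            aligned = center_star_msa([s.residues.replace("*", "X") for s in seeds])
            msa = pyhmmer.easel.TextMSA(
                name=name.encode(),
                sequences=[
                    pyhmmer.easel.TextSequence(name=s.id.encode(), sequence=row)
                    for s, row in zip(seeds, aligned)
                ],
            )
            hmm, _, _ = builder.build_msa(msa.digitize(abc), background)
            rows = tuple(aligned)
        import tempfile

        tmp = tempfile.NamedTemporaryFile(
            suffix=".hmm", prefix=f"{name}_", delete=False
        )
        with tmp:
            hmm.write(tmp, binary=False)
        return ProfileModel(
            name=name,
            length=hmm.M,
            kind="external-file",
            path=Path(tmp.name),
            msa_depth=len(seeds),
            msa_rows=rows,
            msa_ids=tuple(s.id for s in seeds),
        )

    def _load_hmms(self, path: Path):
        with self._pyhmmer.plan7.HMMFile(path) as fh:
            return list(fh)

    def search(
        self,
        profile: ProfileModel,
        dataset: Sequence[SequenceRecord],
        params: SearchParams,
    ) -> list[DomainHit]:
        if profile.kind != "external-file" or profile.path is None:
            raise UsageError("hmmer backend can only search file-backed profiles")
        if not dataset:
            raise UsageError("search_profile needs a non-empty dataset")
        return self.search_db(profile.path, dataset, params)

    def search_db(
        self,
        hmm_path: str | Path,
        dataset: Sequence[SequenceRecord],
        params: SearchParams,
    ) -> list[DomainHit]:
        """Search every profile in a database file against the dataset."""
        pyhmmer = self._pyhmmer
        abc = pyhmmer.easel.Alphabet.amino()
        targets = pyhmmer.easel.DigitalSequenceBlock(
            abc,
            [
                pyhmmer.easel.TextSequence(
                    name=rec.id.encode(),
                    description=rec.description.encode(),
                    sequence=rec.residues.replace("*", "X"),
                ).digitize(abc)
                for rec in dataset
            ],
        )
        hmms = self._load_hmms(Path(hmm_path))
        buf = io.BytesIO()
        header = True
        for tophits in pyhmmer.hmmer.hmmsearch(hmms, targets, cpus=1, E=10.0):
            tophits.write(buf, format="domains", header=header)
            header = False
        buf.seek(0)
        import tempfile

        with tempfile.NamedTemporaryFile(
            suffix=".domtblout", mode="wb", delete=False
        ) as tmp:
            tmp.write(buf.getvalue())
        hits = read_domtblout(tmp.name)
        Path(tmp.name).unlink()
        return [
            h
            for h in hits
            if h.c_evalue < params.evalue_max
            and h.i_evalue < params.evalue_max
            and h.acc >= params.acc_min
        ]


_BACKENDS = {"builtin": BuiltinBackend, "hmmer": HmmerBackend}


def get_backend(name: str):
    """Instantiate a backend by name ('builtin' or 'hmmer')."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise UsageError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls()


def build_profile(
    seeds: Sequence[SequenceRecord], name: str, backend: str | object = "builtin"
) -> ProfileModel:
    """Align seeds and build a profile with the chosen backend."""
    be = get_backend(backend) if isinstance(backend, str) else backend
    return be.build(seeds, name)


def search_profile(
    profile: ProfileModel,
    dataset: Sequence[SequenceRecord],
    params: SearchParams = SearchParams(),
    backend: str | object | None = None,
) -> list[DomainHit]:
    """Search a profile against a dataset, returning filtered domain hits."""
    if backend is None:
        backend = "builtin" if profile.kind == "builtin-pssm" else "hmmer"
    be = get_backend(backend) if isinstance(backend, str) else backend
    return be.search(profile, dataset, params)
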