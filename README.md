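# archminer

Custom genome mining by protein domain architecture. `archminer` is a
Python package and command-line toolkit for finding the members of a
protein family you define yourself — for example the key enzymes of
fungal secondary metabolism (polyketide synthases, non-ribosomal peptide
synthetases, their hybrids, dimethylallyl tryptophan synthases) — in any
protein dataset such as a predicted proteome. It consists of two
complementary engines:

* **Profile enrichment** (`iterhmmbuild`). Starting from a handful of
  seed sequences of a domain of interest, it builds a profile, searches
  it against a protein dataset, merges the matching regions into the
  seed set, removes redundancy by greedy clustering at 90% identity,
  rebuilds the profile, and repeats. The loop stops when the seed count
  is unchanged between iterations, or when a convergence counter — which
  increments every iteration that adds at most one sequence (or loses
  some) — reaches its limit of 3. Individual enriched profiles can be
  concatenated into a searchable profile database.

* **Annotation and rule-based classification** (`prosecda`). Domains
  from a profile database are assigned to proteins; hits are kept when
  both the conditional and the independent per-domain E-value are below
  0.01 and the expected per-residue alignment accuracy is at least 0.6.
  Overlapping hits (sharing at least 40% of the shorter hit) are
  resolved into the *most-likely domain architecture*: the subset of
  pairwise non-overlapping hits maximizing the total score, where each
  hit scores −log₁₀(i-Evalue) (the HMMER bit score when the E-value
  underflows to 0). Proteins are then classified into user-defined
  families by YAML rules listing mandatory domains (optionally with
  per-domain E-value ceilings) and forbidden domains.

Profile building and searching run either through
[pyhmmer](https://pyhmmer.readthedocs.io) (in-process HMMER3, the
default) or through a self-contained position-specific scoring backend
with empirical E-values, which needs no profile-HMM machinery and keeps
the whole pipeline deterministic for testing.

## Worked example

Generate a synthetic proteome with planted domain architectures and its
matching hit table, scaffold a rules file, and classify:

```bash
archminer fixtures -out demo --seed 4
archminer rules-init demo/rules.yaml
prosecda -proteins demo/dataset.fa -rules demo/rules.yaml \
         --hits demo/dataset.domtblout -out demo/out
```

which prints `results written to demo/out`, and `demo/out/summary.tsv`
begins:

```
protein_id	rule	n_domains	total_score	domain_string
PKS-NRPS_1	PKS-NRPS	5	108.455	KS|AT|PP-binding|C|A
PKS-NRPS_2	PKS-NRPS	5	59.9608	KS|AT|PP-binding|C|A
```

One row per (protein, matched family): `PKS-NRPS_1` carries all five
mandatory domains of the hybrid rule in its most-likely architecture;
`n_domains` counts the architecture's domains and `total_score` is the
summed −log₁₀(i-Evalue) over them. The fixture's ten complete PKS
proteins appear under rule `PKS`, the five missing their PP-binding
domain under `PKS-like`, and the ten shuffled decoys match nothing.
Per-protein XML summaries and FASTA files are written under
`demo/out/results/<rule>/`.

The enrichment engine runs the same way from the shell:

```bash
iterhmmbuild -seq seeds.fa -db proteome.fa -out enriched/ --backend hmmer
```

writing the final profile (`seeds.hmm`), the final seed set
(`seeds_seed.fa`), its alignment (`seeds_seed.clw`), per-iteration
snapshots (`iter_i/`) and a run log. Giving `-seq` a directory of FASTA
files enriches each family independently and concatenates the profiles
into `database.hmm`.

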