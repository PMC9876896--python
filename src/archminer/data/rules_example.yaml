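# Example family rules for secondary-metabolism key enzymes.
#
# Domain names: KS ketoacyl synthase, AT acyl transferase, PP-binding
# phosphopantetheine binding, C condensation, A adenylation, Trp_DMAT
# dimethylallyl tryptophan synthase.
#
# Complete enzymes require all essential domains; "-like" families carry
# all but one; forbidden lists keep hybrids (both module types) out of
# the pure families and pure enzymes out of the "-like" bins.
rules:
  - name: PKS
    comment: polyketide synthase, all three essential domains
    mandatory: [KS, AT, PP-binding]
    forbidden: [C, A]
  - name: PKS-like
    comment: PKS missing one essential domain (KS and AT present)
    mandatory: [KS, AT]
    forbidden: [PP-binding, C, A]
  - name: NRPS
    comment: non-ribosomal peptide synthetase
    mandatory: [A, C, PP-binding]
    forbidden: [KS, AT]
  - name: NRPS-like
    comment: NRPS missing one essential domain (A and C present)
    mandatory: [A, C]
    forbidden: [PP-binding, KS, AT]
  - name: PKS-NRPS
    comment: hybrid carrying both full modules
    mandatory: [KS, AT, PP-binding, A, C]
  - name: dom_A
    comment: isolated adenylation domain only
    mandatory: [A]
    forbidden: [C, PP-binding, KS, AT, Trp_DMAT]
  - name: DMATS
    comment: dimethylallyl tryptophan synthase
    mandatory: [Trp_DMAT]
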