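# Small demonstration cohort: two groups, three 4-fold dysregulated piRNA
# loci, somatic-like biogenesis. Used by the README walkthrough and the
# end-to-end determinism check.
seed: 42
simulate:
  libsize_mean: 900
  n_pirna_loci: 30
  groups:
    - name: control
      n_samples: 4
    - name: PD
      n_samples: 4
      fold_change:
        piR-sim-0001: 4.0
        piR-sim-0002: 4.0
        piR-sim-0003: 4.0
presence_rule:
  min_all: 2
  min_half: 5
de_groups: [control, PD]
component_grid: [1, 2, 3]
keepx_grid: [5, 10, 25]
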