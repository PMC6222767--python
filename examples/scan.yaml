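# Convergence-scan configuration for `qmmm-embed scan --config examples/scan.yaml`.
# Models x switching schemes x cutoffs, RMSDs over re-seeded synthetic
# solvation boxes against the all-charge density-embedding reference.
solute: formate          # built-in name or path to an xyzq file
n_configs: 10
waters: 200
box: 30.0                # cube edge, Angstrom
bias: anion              # hydrogen-toward-solute orientation bias
seed: 1
backend: rhf
n_states: 1              # lowest CIS excitations compared per cell
models: [truncation, truncation_mmlc, espc, espcd]
switchings: [step, lrec, switch]
cutoffs: [5.0, 10.0, 15.0]
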