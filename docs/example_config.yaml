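# Annotated configuration schema for `tagdistort simulate --config <file>`.
# Every key is optional; omitted keys take the defaults shown here. Unknown
# keys are rejected at load time. Explicit command-line flags override the
# config. All stochastic runs are fully determined by `seed`.

model:
  kind: multiplicative     # multiplicative | dominant | recessive | general | interaction
  hom_rr: 1.96             # homozygous relative risk; sets beta = 0.5*log(hom_rr)
  # beta: 0.336            # alternatively, explicit log-scale parameters
  # gamma: 0.0             # (required for kind: general)
  # beta1: 0.0             # interaction-model parameters (kind: interaction)
  # beta2: 0.0
  # tau: 0.0
  mu: -4.605170185988091   # baseline log risk, log(0.01)
  raf: 0.3                 # risk allele frequency for analytic subcommands

ld:                        # optional two-locus LD block (analytic subcommands)
  f_a: 0.3                 # causal-SNP allele-1 frequency
  f_b: 0.3                 # marker-SNP allele-1 frequency
  r: 1.0                   # haplotype correlation; validated against the
                           # feasible interval implied by (f_a, f_b)

design:
  n_case: 2000             # cases per stage
  n_ctrl: 2000             # controls per stage

thresholds:
  scan: 1.0e-6             # genome-scan trend-test threshold
  replication: 0.01        # replication trend-test threshold
  deviation: 0.05          # deviation-test significance level

panel:                     # synthetic haplotype panel
  n_hap: 100000            # phased haplotypes
  n_snp: 1000              # SNPs in the region
  region_bp: 500000        # region length (bp)
  ld_decay: 2.0e-5         # per-bp LD decay rate
  n_founders: 100          # mosaic founder pool size
  mutation_rate: 0.002     # per-allele copy-error probability
  chip_maf: 0.05           # minimum MAF for chip eligibility
  chip_prob: 0.5           # retention probability of eligible SNPs

seed: 0                    # master seed; per-study seeds are spawned from it
out: null                  # output prefix for the simulate subcommand
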