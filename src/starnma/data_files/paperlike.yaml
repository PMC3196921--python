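# Default "paperlike" simulation scenario: a star-shaped network of
# placebo-controlled osteoporosis trials for nine drugs, sized like the
# published nine-drug evidence base (30 trials, ~59,000 patients, i.e. about
# 1,000 patients per arm), with per-outcome true odds ratios set to the
# published per-drug posterior means and overall placebo event rates taken
# from the published per-outcome placebo-rate column. Drugs with no published
# data for an outcome (NR cells) are absent from that outcome's network.
name: paperlike
arm_size: 1000
baseline_logit_sd: 0.4
tau: 0.0
studies_per_drug:
  alendronate: 6
  denosumab: 1
  etidronate: 8
  ibandronate: 4
  raloxifene: 1
  risedronate: 6
  strontium: 2
  teriparatide: 1
  zoledronic: 1
outcomes:
  nonvertebral:
    placebo_rate: 0.105
    true_or:
      alendronate: 0.81
      denosumab: 0.80
      etidronate: 0.64
      ibandronate: 0.90
      raloxifene: 0.91
      risedronate: 0.77
      strontium: 0.86
      teriparatide: 0.62
      zoledronic: 0.74
  vertebral:
    placebo_rate: 0.110
    true_or:
      alendronate: 0.51
      denosumab: 0.31
      etidronate: 0.61
      ibandronate: 0.50
      raloxifene: 0.63
      risedronate: 0.60
      strontium: 0.59
      teriparatide: 0.32
      zoledronic: 0.28
  hip:
    placebo_rate: 0.019
    true_or:
      alendronate: 0.59
      denosumab: 0.67
      etidronate: 1.02
      raloxifene: 1.29
      risedronate: 0.78
      strontium: 0.98
      teriparatide: 0.71
      zoledronic: 0.65
  wrist:
    placebo_rate: 0.031
    true_or:
      alendronate: 0.93
      etidronate: 2.42
      raloxifene: 1.76
      risedronate: 0.91
      strontium: 3.25
      teriparatide: 1.23
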