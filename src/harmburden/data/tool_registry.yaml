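# Default registry of the 12 in-silico deleteriousness predictors.
#
# Each tool's raw output is mapped to one of three levels:
#   D  deleterious
#   P  probably deleterious
#   T  tolerable
#   NA explicitly uninformative (counted as missing, never as tolerable)
#
# Categorical maps follow each tool's published code conventions as emitted
# in ANNOVAR *_pred columns. CADD is the only numeric tool: PHRED-scaled
# score >= 15 is deleterious, below is tolerable (no P level).
tools:
  SIFT:
    kind: categorical
    map: {D: D, T: T}
  Polyphen2_HDIV:
    kind: categorical
    map: {D: D, P: P, B: T}
  Polyphen2_HVAR:
    kind: categorical
    map: {D: D, P: P, B: T}
  LRT:
    kind: categorical
    map: {D: D, N: T, U: NA}
  MutationTaster:
    kind: categorical
    map: {A: D, D: D, N: T, P: T}
  MutationAssessor:
    kind: categorical
    map: {H: D, M: P, L: T, N: T}
  FATHMM:
    kind: categorical
    map: {D: D, T: T}
  PROVEAN:
    kind: categorical
    map: {D: D, N: T}
  fathmm-MKL_coding:
    kind: categorical
    map: {D: D, N: T}
  MetaSVM:
    kind: categorical
    map: {D: D, T: T}
  MetaLR:
    kind: categorical
    map: {D: D, T: T}
  CADD:
    kind: numeric_threshold
    threshold: 15.0
    direction: ge
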