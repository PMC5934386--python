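# Standard side-chain accessible surface areas (A^2) in Gly-X-Gly
# tripeptides (Miller et al., J Mol Biol 1987).  Used as the default scale
# for rate-vs-ASA trend regressions; substitute any other scale via
# load_asa_table(path).
asa_A2:
  A: 67.0
  R: 196.0
  N: 113.0
  D: 106.0
  C: 104.0
  Q: 144.0
  E: 138.0
  G: 0.0
  H: 151.0
  I: 140.0
  L: 137.0
  K: 167.0
  M: 160.0
  F: 175.0
  P: 105.0
  S: 80.0
  T: 102.0
  W: 217.0
  Y: 187.0
  V: 117.0
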