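# External test-set pIC50 predictions of the three published models (PLS, GA-PLS,
# stepwise MLR), transcribed verbatim.  Residual convention: predicted - experimental.
# Row 47's printed residuals disagree with its printed experimental/predicted pair by
# 0.03-0.04 (see NOTES.md).
compound_id,pic50_exp,pls_pred,pls_resid,gapls_pred,gapls_resid,smlr_pred,smlr_resid
10,7.24,7.34,0.10,6.79,-0.45,7.42,0.18
12,6.50,6.32,-0.17,6.71,0.22,6.35,-0.14
17,7.50,7.44,-0.06,7.82,0.32,7.26,-0.24
2,7.20,7.80,0.60,8.31,1.11,7.67,0.47
21,6.34,6.64,0.30,6.67,0.33,6.68,0.35
25,6.00,6.51,0.51,6.52,0.52,6.10,0.10
25a,8.70,7.81,-0.89,8.72,0.02,7.85,-0.84
37b,6.58,6.46,-0.13,6.57,-0.01,6.16,-0.43
40,5.70,5.73,0.03,6.00,0.30,5.28,-0.42
43,6.00,5.52,-0.48,5.78,-0.22,5.65,-0.35
45b,5.96,5.22,-0.73,5.60,-0.36,6.55,0.59
47,6.14,6.80,0.62,6.70,0.52,5.60,-0.57
51,6.45,6.58,0.12,6.30,-0.15,6.10,-0.35
53b,6.85,6.45,-0.41,6.61,-0.24,6.30,-0.56
58c,8.39,7.60,-0.79,7.31,-1.08,7.67,-0.71
6,7.92,8.50,0.58,7.64,-0.28,8.21,0.29
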