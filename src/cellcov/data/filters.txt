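# Named analysis filter sets for the dual-tree complex wavelet transform.
#
# Each set provides:
#   h0o, h1o : odd-length biorthogonal low/high analysis pair for level 1
#              (tree b reuses the same pair delayed by one sample, which is
#              the required half-sample offset after decimation);
#   h0a      : even-length orthonormal quarter-shift lowpass for levels >= 2
#              (tree a; tree b uses its time reverse, the highpass filters
#              follow by quadrature mirroring).
#
# bior97_qshift14: Cohen-Daubechies-Feauveau 9/7 analysis pair at level 1,
# Kingsbury's 14-tap quarter-shift orthonormal filter at levels >= 2.

[bior97_qshift14]
h0o = 0.03782845550726404 -0.023849465019556843 -0.11062440441843718 0.37740285561283066 0.8526986790088938 0.37740285561283066 -0.11062440441843718 -0.023849465019556843 0.03782845550726404
h1o = -0.06453888262869706 0.04068941760916406 0.41809227322161724 -0.7884856164055829 0.41809227322161724 0.04068941760916406 -0.06453888262869706
h0a = 0.00325314 -0.00388321 0.03466035 -0.03887280 -0.11720389 0.27529538 0.75614564 0.56881042 0.01186609 -0.10671180 0.02382538 0.01702522 -0.00543948 -0.00455690
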