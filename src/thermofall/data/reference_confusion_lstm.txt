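# Reference confusion matrix: LSTM classifier on the six handcrafted
# features, pooled over 8-fold subject-grouped cross-validation of the
# original 16-participant study (800 samples per true class).
# Rows = true class, columns = predicted class.
falling sit2stand stand2sit sitting standing bowing crouching walking
falling    740   3  21   6   8   4   1  17
sit2stand   26 724   9   0   9   7  14  11
stand2sit   37   1 694  38   5   3  19   3
sitting      4   0   1 626  26  97  35  11
standing     7   0   0  18 630  80  57   8
bowing       5   3   1  26  16 649  98   2
crouching    0   4   4  32  22 138 593   7
walking      2  41   7  15  10  45  50 630
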