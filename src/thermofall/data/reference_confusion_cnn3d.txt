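# Reference confusion matrix: 3D CNN classifier on raw 15-frame windows,
# pooled over 8-fold subject-grouped cross-validation of the original
# 16-participant study (800 samples per true class).
# Rows = true class, columns = predicted class.
falling sit2stand stand2sit sitting standing bowing crouching walking
falling    748   0   0   0   0   0   0  52
sit2stand    0 720   0  28   4   0   0  48
stand2sit    5   0 793   2   0   0   0   0
sitting      0   0   0 745  51   0   0   4
standing     0   0   0  19 769   0   0  12
bowing       0   8   0   8   7 721  42  14
crouching    0   0   0  23   0   5 765   7
walking     23   4   0   0   0   0   6 767
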