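"""Arithmetic-operation budget of the deployed detector per 1-s epoch.

Prints, for each encoder hidden size, the data reduction, the encoder
(feature extraction) operation count and the Gaussian-SVM decision
count — the numbers that determine whether the pipeline fits a wearable
compute budget.
"""

from seizae import ae_op_count, data_reduction, svm_op_count

n = 256  # samples per 1-s epoch at 256 Hz
print(f"{'hidden':>6} {'reduction':>12} {'AE ops':>8} {'SVM ops':>8}")
for m in (64, 32, 20, 16, 8):
    red, cr = data_reduction(n, m)
    print(f"{m:>6} {red:>9.2f}% ({cr:g}) {ae_op_count(n, m).total:>8} "
          f"{svm_op_count(m).total:>8}")
# AE ops = m*(2n-1): each hidden unit is an n-sample dot product
# (n multiplications, n-1 additions; the decoder is discarded at test
# time). The SVM column is the per-decision budget at that feature size.
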