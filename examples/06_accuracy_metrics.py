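"""Confusion-matrix accuracy metrics for a classified map.

Rows are the mapped class, columns the reference class; producer accuracy
(omission errors) is column-wise, user accuracy (commission errors)
row-wise. These are the standard figures quoted for remote-sensing land-use
products (e.g. OA near 0.9 and kappa near 0.85 for a good 10 m map).
"""

from esvgrid import confusion_matrix_metrics

labels = ["cropland", "woodland", "grassland", "water", "urban"]
matrix = [
    [182,   6,  10,  0,  2],   # mapped cropland
    [  4, 151,  12,  0,  0],   # mapped woodland
    [ 14,  10, 169,  1,  0],   # mapped grassland
    [  0,   0,   2, 48,  0],   # mapped water
    [  3,   0,   1,  0, 85],   # mapped urban
]
res = confusion_matrix_metrics(matrix, labels=labels)
print(f"overall accuracy: {res['OA']:.4f}   kappa: {res['kappa']:.4f}")
print(f"{'class':>10} {'PA':>7} {'UA':>7}")
for lab in labels:
    print(f"{lab:>10} {res['PA'][lab]:7.4f} {res['UA'][lab]:7.4f}")
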