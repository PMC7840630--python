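"""Lay out a pooled-QC bracketed batch design.

Builds the injection sequence for a 64-sample study: each batch opens with
seven QC injections (five of them equilibration runs excluded from drift
fitting), closes with two QCs, and brackets every segment of four randomly
ordered samples with QCs, within a 95-injection batch limit.
"""
import lcmsqc as L
from lcmsqc.tables import records_to_frame

design = L.generate_batch_design([f"sample{i:02d}" for i in range(64)], seed=1)
meta = records_to_frame(design)

n_qc = (meta["sample_type"] == "QC").sum()
usable = meta["usable_for_drift"].astype(bool).sum()
print(f"injections total : {len(meta)}")
print(f"QC injections    : {n_qc} ({usable} usable for drift fitting)")
print(f"batches          : {meta['batch_id'].nunique()}")
print("first 10 of the sequence:", list(meta.index[:10]))
# 88 injections = 64 samples + 24 QCs; 19 usable QCs trace the drift curve.
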