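"""Generate a labeled synthetic accelerometer dataset and inspect it.

Builds 10 fall and 10 ADL records at 100 Hz from the built-in activity
templates (three-phase falls, broken falls, falls preceded by an ADL,
sit-downs, walking, quiet activities) and prints the manifest plus the AVM
peak of each record.  Fall impact peaks land in the configured 2-8 g range;
low-peak ADL stay near the 1 g rest level.
"""

import numpy as np

import fallseg as fs

cfg = fs.GeneratorConfig(
    sampling_rate_hz=100.0, n_fall_records=10, n_adl_records=10, seed=1
)
records, manifest = fs.generate_dataset(cfg)

print(manifest[["record_id", "activity_type", "class", "fs_hz"]].to_string(index=False))
print()
for rec in records[:5]:
    avm = fs.compute_avm(rec)
    print(
        f"{rec.record_id} ({rec.activity_type:>14}): {rec.duration_s:5.1f} s, "
        f"max AVM {avm.values.max():.2f} g  (1 g = rest level)"
    )
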