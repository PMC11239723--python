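"""Generate a small synthetic 12-lead ECG cohort and verify its morphology.

Builds 40 records (500 Hz, 4096 samples) with the four-class abnormality mix,
then re-measures each record's class-defining quantity with the independent
fiducial estimators.  The printed table shows that labeled morphology
(PR interval, RR irregularity, QRS width, lead asymmetry) is actually present
in the waveforms, not just in the labels.
"""

import numpy as np

from cardiossm import measurements as M
from cardiossm.ecg_io import decode_labels
from cardiossm.synthetic_ecg import SyntheticCohortConfig, synth_dataset

config = SyntheticCohortConfig(n_records=40, seed=11)
records, manifest = synth_dataset(config)

print(f"cohort: {len(records)} records, "
      f"{records[0].n_leads} leads x {records[0].n_samples} samples "
      f"@ {records[0].sampling_rate:g} Hz")
print("label counts:", manifest["labels"].replace("", "normal")
      .value_counts().to_dict())
print()
print(f"{'record':>10s} {'labels':>12s} {'PR s':>7s} {'RR-CV':>6s} "
      f"{'QRS s':>6s} {'ST mV':>6s} {'V1/V6':>6s} checks")
for rec in records[:10]:
    w = M.measure_qrs_widths(rec)
    print(f"{rec.record_id:>10s} {';'.join(decode_labels(rec.labels)) or '-':>12s} "
          f"{M.measure_pr_interval(rec):7.3f} "
          f"{M.rr_coefficient_of_variation(rec):6.3f} "
          f"{np.median(w):6.3f} {M.measure_st_level(rec):+6.2f} "
          f"{M.qrs_amplitude_ratio_v1_v6(rec):6.2f} "
          f"{M.class_checks(rec) or 'n/a (normal)'}")
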