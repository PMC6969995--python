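"""Train and evaluate the binary fatigue classifier on a synthetic cohort.

Builds 28-entry feature vectors (mean normalized level + relative
variation rate for each of the 14 descriptors) from the early and late
halves of each subject's trial, evaluates with participant-grouped
11-fold cross-validation, and streams one trial through the trained model
to watch the nonfatigued certainty decay.

Takes about a minute: every trial runs the full event-detection and
descriptor-extraction pipeline.
"""
import numpy as np

import fatiguekit as fk
from fatiguekit import classify as clf

params = [r.param_id for r in fk.reference.REFERENCE_TRENDS]
base = fk.synth.SyntheticTrialSpec(duration_s=300.0)
members = fk.synth.synth_cohort(11, base, seed=2024)

cohort = {}
for m in members:
    sig, _ = fk.synth.synth_emg(m.plus)
    tach, _ = fk.synth.synth_rr(m.plus)
    cohort[m.participant_id] = fk.pipeline.trial_ifd_series(
        sig, tach, m.participant_id)

maxima = clf.calibration_maxima(cohort)
examples = clf.build_training_set(cohort, maxima, params)
print(f"{len(examples)} training examples x {examples[0].features.size} features")

report = clf.evaluate(examples, k=11, seed=1)
print(f"11-fold accuracy: {report.mean_accuracy:.2f} "
      f"[{report.ci95[0]:.2f}; {report.ci95[1]:.2f}]")

model = clf.train_svm(examples)
pid = members[0].participant_id
stream = clf.classify_stream(model, cohort[pid], maxima[pid], params,
                             window_s=60.0)
slope = np.polyfit(stream["t"], stream["p_nonfatigued"], 1)[0]
print(f"\nstreaming {pid}: nonfatigued probability "
      f"{stream['p_nonfatigued'].iloc[0]:.2f} -> "
      f"{stream['p_nonfatigued'].iloc[-1]:.2f} "
      f"(slope {slope:+.2e} per s)")
# High cross-validated accuracy reflects the programmed separation between
# early and late trial segments; the streamed nonfatigued probability
# declines as the trial progresses, mirroring fatigue onset.
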