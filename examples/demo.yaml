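# Demo pipeline configuration: a reduced synthetic benchmark that runs the
# five pipeline stages end to end in a few minutes on one CPU.
# Windows follow the default per-metric observation-window table
# (SDNN/RMSSD/SampEn/CSI/CVI: 60 s; LF/HF: 180 s), step 10 s, Wp 60 s.
n_seizures: 4
seizure_duration_s: 1020.0
preictal_onset_s: 780.0
preictal_ramp_s: 180.0
n_interictal_records: 2
interictal_duration_s: 1500.0
horizon_s: 300.0
seed: 7
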