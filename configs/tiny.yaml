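# Desk-scale demo configuration: 3 records/class of 20 s at 250 Hz,
# reduced-width model, one training epoch.  For a realistic run raise
# n_per_class, sim.duration_s (the study condition is 300 s records) and
# train.epochs, and switch model_preset to "default".
n_per_class: 3
seed: 0
model_preset: tiny
sim:
  fs: 250.0          # sampling rate (Hz); the reference stride of 250
  duration_s: 20.0   # samples corresponds to 1 s at this rate
preprocess: {}       # 0.05-30 Hz 4th-order Butterworth, 0.04 s smoother,
                     # wavelet+spline baseline correction, min-max
augment: {}          # 10 s windows; S_ref=250, S_min=125, S_max=500, beta=1
welch:
  n_bands: 16        # self-similarity matrix size (bands x bands)
train:
  epochs: 1
  batch_size: 30     # protocol default is 60 with lr 5e-4 for 160 epochs
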