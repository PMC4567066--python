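{
 "version": "transfer_svm_v1",
 "feature_names": [
  "template_xcorr",
  "peak_valley_dt",
  "orientation_deg",
  "intensity_before",
  "intensity_after",
  "altitude_delta_m"
 ],
 "classes": [
  "none",
  "sit_to_stand",
  "stand_to_sit"
 ],
 "coef": [
  [
   0.6197874393408016,
   0.6116420705047753,
   -0.2680861048000676,
   0.05190553100509498,
   0.1169541085220817,
   -0.5516327561659483
  ],
  [
   0.24256360207696426,
   -0.03447702953739291,
   -0.05439172780429026,
   -0.06885580934908299,
   0.03172464683749519,
   1.32633274385304
  ],
  [
   -0.22048382574631917,
   -0.10506310042067696,
   0.03379043690496031,
   0.05882193713457778,
   -0.03645000504153189,
   -1.2804818515136724
  ]
 ],
 "intercept": [
  0.3178567690341229,
  -1.2631880261053483,
  -1.267171247985924
 ],
 "scaler_mean": [
  0.055136718426328814,
  1.2416666666666685,
  9.733381200506882,
  0.049241171453368954,
  0.05097568053490725,
  -0.002058675726668472
 ],
 "scaler_scale": [
  0.6877448865752208,
  0.7843263918094864,
  12.16718843426662,
  0.041231398667864,
  0.04010149286645236,
  0.28506307490725147
 ],
 "training_seed": 20150911,
 "n_training_samples": 600
}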