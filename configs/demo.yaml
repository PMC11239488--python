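# Demo pipeline run: small photometry session -> dF/F -> trials -> AUC ->
# mixed model + waveform windows. Completes in well under two minutes.
seed: 7
stage: photometry
out_dir: results/demo
photometry:
  session_length: 1500
  event_counts:
    stim_20hz: 4
    stim_50hz: 4
    food: 4
  iti_mean: 100
waveform:
  B: 500
  n_perm: 500
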