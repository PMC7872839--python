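# File formats

## Raw session export

Tab-separated UTF-8 text, decimal point `.`, one row per frame at fixed
6-decimal precision. Optional `#`-prefixed metadata preamble
(`duration_setting` in seconds, `nominal_rate` in frames/s, `label`),
then a header row, then the data. `valid` is 1 when the face was tracked
in that frame; coefficients of untracked frames are ignored by scoring.

```text
# duration_setting: 10
# nominal_rate: 60
timestamp	brow_raise_left	brow_raise_right	eye_closure_left	eye_closure_right	mouth_corner_lift_left	mouth_corner_lift_right	valid
0.000000	0.000000	0.000000	0.000000	0.000000	0.000000	0.000000	1
0.016667	0.000197	0.000197	0.000000	0.000000	0.000000	0.000000	1
```

Sides are the *subject's* anatomical left/right; resolve any selfie
mirroring before export. ARKit-style column names (`browOuterUpLeft`,
`browInnerUpRight`, `eyeBlinkLeft`, `mouthSmileRight`, …) are accepted as
aliases on read. Timestamps must be strictly increasing. Write-then-read
reproduces a session exactly at the printed precision.

## History store

One JSON object per line, append-only: `recorded_at` (ISO-8601), `label`,
`dfi_left`, `dfi_right`, and the per-region `delta_rel` breakdown. JSON
round-trips IEEE doubles exactly, so reloading reproduces stored values
bit for bit.

## Scenario files

YAML mapping of `SimulationScenario` fields (see `docs/methods.md`);
regions are `forehead` / `eyes` / `mouth`, sides `left` / `right`.
Unknown keys are rejected. Example:

```yaml
duration: 10.0
weakness: {forehead: 1.0, eyes: 1.0, mouth: 0.5}
affected_side: left
noise_sd: 0.02
seed: 7
```
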