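# Methods

## The detection model

`wheezekit` treats a wheeze as a narrow, temporally persistent ridge in the
short-time power spectrum of the chest-microphone signal: per the CORSA
definitions, a dominant frequency above 100 Hz sustained for more than
100 ms, typically inside 100–5000 Hz. Detection proceeds in five stages —
preprocessing, short-time Fourier analysis, per-frame thresholding of local
spectral maxima, cross-frame linking into candidate tracks, and track
classification against the noise classes heard in a pediatric consultation
room (heartbeats, ambient voices, crying). The second microphone, facing the
room rather than the chest, provides the reference that separates ambient
sources from chest sources.

Key assumptions: the wheeze is quasi-stationary in frequency over the
372 ms analysis window; interference is either brief (heartbeats), ambient
(voices), or spectro-temporally unstable/broadband (crying); and relative
levels — not absolute calibration — carry the information, so every
threshold is set relative to the frame's own band level and the pipeline is
invariant to global gain.

## Parameters

| Parameter | Default | Why |
| --- | --- | --- |
| target rate | 11 025 Hz | analysis standard; Nyquist comfortably above the 5 kHz band edge |
| passband | 50–5500 Hz | just outside the 90–5000 Hz thresholding band so filter skirts do not shape it |
| filter | Butterworth order 4, zero-phase | flat passband; zero phase keeps onsets in place for the 100 ms rule |
| window | Hamming, 4096 pts (372 ms) | 2.7 Hz bins resolve closely spaced wheeze tones |
| hop | 128 pts (11.6 ms) | temporal resolution of the duration rule |
| threshold band | 90–5000 Hz | overall sound-pressure reference band |
| threshold offset | +10 dB over band mean | separates tonal ridges from the breath-noise floor |
| candidate band | 100–5000 Hz | CORSA wheeze frequency range |
| min duration | > 100 ms (strict) | CORSA minimum; 9 frames (104.5 ms) pass, 8 (92.9 ms) fail |
| max duration | 3000 ms | proxy cap for "within one expiration"; observed wheezes reach 1616 ms |
| drift / gap | ±3 bins/frame, ≤ 2 frames | tolerance of the greedy nearest-frequency linker |
| heartbeat rule | duration ≤ 100 ms | heart sounds are briefer than the minimum wheeze |
| voice rule | env − lung ≥ 0 dB | ambient sources are at least as loud on the environment microphone |
| crying rules | freq CV > 0.15, gap fraction > 0.3, crowding > 2.5 | unstable contour, fragmented pattern, or many comparable-level neighbors |
| intensity rule | mean margin ≥ 6 dB | rejects faint floor excursions; see below |

All cutoffs live in `RuleThresholds` and the stage configs and are
overridable; `fit_tree` trains a depth-≤ 4 decision tree on labeled tracks
as an alternative classifier with the same audit trail.

## dB convention and thresholding statistics

Spectra are amplitude-normalized by the window's coherent gain, so a
full-scale bin-centered sine reads 0 dB; all downstream decisions use level
*differences*, so the reference cancels. One statistical fact shapes the
classifier: for a Gaussian noise floor the periodogram is exponentially
distributed per bin, so the +10 dB threshold sits a fixed ≈ 7.5 dB above the
floor's dB-mean and a few floor bins cross it in *every* frame regardless of
the floor level. Because consecutive windows overlap by 97%, those
excursions persist across frames and form retained tracks of 100–400 ms.
They are, however, faint: measured over 180 noise-only synthetic scenes,
their mean margin above threshold never exceeded 3.5 dB, while a wheeze only
10 dB above the floor (broadband RMS) stands ≈ 40 dB above threshold thanks
to the 4096-point window's processing gain. The minimum-intensity rule
(default 6 dB) was calibrated on those noise-only fixtures to reject floor
excursions with a wide margin on both sides. Recorded wheeze intensities in
the study population start at 3 dB; on real (non-flat, non-Gaussian)
material the cutoff can be lowered accordingly.

## The crowding feature

A loud short vocalization is smeared by the 372 ms window into a broad
time–frequency plateau whose internal maxima link into tracks with *stable*
frequency contours — frequency CV and gap fraction cannot see the
difference from a wheeze. What does distinguish them is sparseness: a wheeze
is a solitary ridge (typically at most two simultaneous local maxima),
whereas a plateau carries many comparable-level maxima side by side.
`peak_crowding` is the mean number of other peaks within ±25 bins (±67 Hz)
and 15 dB of each track point, averaged over the track's *core* points
(within 20 dB of its loudest point — window smearing extends every track
into faint ramp tails where even a clean tone sits among floor peaks, so
tails are excluded). Wheezes score ≲ 2 even when a polyphonic partner tone
lies within the window (a partner adds exactly 1), while cry plateaus score
upward of ~4; the cutoff of 2.5 sits in that gap.

## What the synthetic scenes emulate — and what they do not

`synthetic_scenes` renders seeded two-channel scenes at 11.025 kHz:

- **Breath noise**: white Gaussian floor at −55 dBFS RMS on each channel,
  independent between channels. Real breath sounds are spectrally sloped
  and respiration-modulated; the flat floor is a deliberate simplification
  that preserves the statistic that matters for thresholding (exponential
  per-bin fluctuation).
- **Wheezes**: Tukey-enveloped sinusoids, frequency 100–1380 Hz, duration
  100–1616 ms, SNR 3–44 dB (the observed ranges), optional equal-amplitude
  partner tone for polyphonic wheezes. SNR is the event's plateau RMS over
  the floor RMS on its native channel, in dB.
- **Heartbeats**: Gaussian-enveloped 45 Hz thumps under 100 ms — below the
  candidate band, with an envelope wide enough that the spectral skirt
  stays out of it.
- **Crying**: chest-dominant three-harmonic phrases whose pitch glides
  through a ±30% arc with ±12% low-passed random jitter (the rough
  phonation of an infant cry).
- **Voices**: environment-dominant five-harmonic bursts with syllabic
  amplitude modulation.
- **Channel coupling**: every event leaks onto the other channel attenuated
  by 12 dB — a fixture constant, not a measured device property.

`sample_corpus` mirrors the study's file split (default 65 wheeze / 149
no-wheeze): wheeze files carry roughly one wheeze per 2.5 s of tidal
breathing (the study observed 813 wheeze sounds across 65 recordings of
30 s), drawn uniformly over the observed parameter ranges with SNR in
[10, 44] dB by default; every file carries 0–3 interference events
(crying 30%, voice 55%, heartbeat 15%, reflecting the reported noise mix
with nasal congestion omitted — no acoustic signature is described for it).

Passing tests on these scenes demonstrates that the pipeline separates
tonal, persistent, chest-dominant, solitary ridges from the modeled
interference classes under realistic level ratios. They do not demonstrate
robustness to sloped or respiration-modulated breath spectra, reverberation,
microphone handling noise, nasal congestion, or wheezes fainter than the
sampled SNR range — real-recording validation is out of scope here.

## Numerical and procedural choices

- Filtering order: anti-aliasing low-pass before resampling, high-pass
  after, both zero-phase (`sosfiltfilt`); rational-ratio resampling with
  `resample_poly`.
- Quantization: rounding to the nearest of 2¹⁶ uniform levels on [−1, 1)
  while keeping a float path.
- Track duration: inclusive frame span × hop (the hop is the resolution at
  which maxima "continue"); the > 100 ms rule is strict.
- Over-long tracks (> 3000 ms) are split at their weakest-margin interior
  point and both halves re-tested, recursively.
- Linking ties: the nearest peak in frequency wins; exact ties go to the
  lower bin. Open tracks claim peaks in order of seniority.
- Polyphonic typing: two wheeze tracks overlapping in time with mean
  frequencies more than one bin apart.
- Jonckheere–Terpstra: ties counted ½; exact permutation enumeration for
  pooled n ≤ 12, else normal approximation with tie-corrected variance and
  a ½ continuity correction; two-sided doubles the smaller tail; entirely
  tied data is degenerate with p = 1 by convention.
- Percentages reported half-up to one decimal.
- Scene lengths: corpus evaluations in the tests and the acceptance script
  use 10 s scenes (with wheeze counts scaled to the same per-breath rate),
  which exercise the identical per-frame pipeline as 30 s recordings.

## Known limitations

- The per-frame threshold admits floor excursions by construction (see
  above); rejection is delegated to the intensity rule rather than the
  thresholding stage.
- Very low-frequency wheezes near 100 Hz sit close to the candidate-band
  edge where the high-pass skirt begins; detection there relies on the
  generous SNR-to-margin gain of the long window.
- Strong tones (margin ≳ 43 dB) raise Hamming sidelobes above threshold;
  the resulting satellite tracks are rejected by the crowding rule but can
  slightly inflate raw candidate counts.
- No respiratory-phase segmentation: the "within one expiration" duration
  cap is a fixed 3000 ms proxy.
- The default rule tree is hand-set from the qualitative class differences;
  the original study's trained tree is not published, so `fit_tree` is
  provided for retraining on labeled material.
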