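# tonerec

Recurrence analysis of two-tone audio signals: synthesize pure-tone,
mistuned-interval and glissando stimuli, quantify their recurrence
structure with a from-scratch recurrence engine, and show that recurrence
peaks of a glissando-against-fixed-tone mixture sit on just-intonation
interval ratios, rank with musical consonance, correlate with the
two-term simplicity index `(m+n)/(m*n)`, and accumulate into a curve that
matches the Devil's staircase of the critical sine circle map.

## Modules

| module | contents |
|---|---|
| `tonerec.synthesis` | `ToneSpec` / `MistunedIntervalSpec` / `GlissandoSpec` / `Signal`, stimulus synthesis, text & 16-bit WAV I/O |
| `tonerec.rqa` | delay embedding, Euclidean distance matrix, radius policies, recurrence plot / percent recurrence, mutual-information lag selection |
| `tonerec.rqe` | sliding-window recurrence scan of the glissando mixture (`RQEConfig`, `RQEProfile`) |
| `tonerec.consonance` | peak detection, rational-interval matching, consonance ranking, simplicity-index correlation, cumulative recurrence |
| `tonerec.circlemap` | sine circle map, winding numbers, mode-locking plateau widths, Devil's staircase, staircase comparison |
| `tonerec.beats` | first-order (envelope) and second-order (vibration-pattern) beat rates |
| `tonerec.pipeline` / `tonerec.cli` | one-shot reproduction pipeline and the `tonerec` command-line interface |

## CLI

```sh
# synthesize the default glissando mixture (360-840 Hz sweep vs 400 Hz)
tonerec synth --kind glissando --out gliss.txt

# sliding-window recurrence profile (window 480, shift 48, m=5, L=3)
tonerec rqe gliss.txt --out profile.tsv

# peaks, consonance ranking, simplicity-index correlation
tonerec analyze profile.tsv --peaks-out peaks.tsv --cumulative-out cum.tsv

# beat rates of a mistuned octave
tonerec synth --kind mistuned --ratio 2/1 --epsilon 3 --duration 2 --out oct.txt
tonerec beats oct.txt

# circle-map staircase at k=1, compared with the empirical profile
tonerec staircase --out stairs.tsv --empirical profile.tsv

# everything at once, with a checksum manifest
tonerec reproduce --out-dir out/
```

## Notes on conventions

- Recurrence uses strict inequality (`distance < radius`) and the
  denominator `N_e (N_e - 1) / 2` over embedded epochs.
- The default scan radius is 10% of each window's mean pairwise distance
  (`fraction_of_mean_distance`, per-window scope); a `global` scope and
  `gaussian_percentile` / `empirical_percentile` / `absolute` policies are
  available.
- Absolute percent-recurrence magnitudes depend on the radius convention;
  peak *positions* and their *rank order* are the stable observables, and
  that is what the acceptance tests assert.
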