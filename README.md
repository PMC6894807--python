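# respibench

Replay a patient's night of breathing on a virtual APAP test bench.

Bench tests of automatic positive airway pressure (APAP) devices
traditionally drive an artificial lung with short, scripted breathing
segments, which cannot reproduce the breath-to-breath variability and event
chronology of a real patient. `respibench` implements the alternative: take
a night-long multichannel sleep polygraph recording (nasal pressure,
respiratory inductance plethysmography (RIP) bands, audio, accelerometer),
turn it breath by breath into the two digital commands a physiological bench
needs, and replay it.

The two commands are:

* **ΔP<sub>mus</sub>** — the simulated respiratory muscular-effort pressure
  driving a single-compartment active lung (compliance *C*, resistance *R*):

  ΔP<sub>mus</sub> = −V<sub>cc</sub>/C − R·V̇<sub>cc</sub>,
  with V<sub>cc</sub> = ∫V̇<sub>cc</sub> dt,

  where V̇<sub>cc</sub> is the estimated *central-command* airflow — the flow
  the brain asked for, which equals the recorded flow except during
  obstructive events, where it is reconstructed at the pre-event baseline
  amplitude;
* **P<sub>ch</sub>** — a per-cycle sealed-chamber pressure for a Starling
  resistor (a collapsible tube mimicking the upper airway), chosen from a
  calibrated attenuation law so the bench airflow amplitude matches the
  recording during obstructive apneas and hypopneas.

Because the physical hardware (ASL 5000 lung simulator, Starling resistor,
DAQ chain) is not at hand, the package ships a software surrogate of it —
the virtual bench — and scores the fidelity of the replayed airflow
V̇<sub>bench</sub> against the recorded V̇<sub>source</sub> with
cycle-by-cycle amplitude and period bias, Bland–Altman limits, per-cycle
Pearson correlation, and apnea-level sensitivity/PPV.

The six processing steps, following standard AASM scoring conventions:

1. resample every channel to 20 Hz, Savitzky–Golay smooth, estimate nasal
   airflow as the signed square root of nasal pressure;
2. segment movement-free ("stable") periods with an adaptive threshold on
   accelerometer frame energy;
3. find every breath onset with multiscale peak detection (AMPD), falling
   back to RIP valleys where airflow excursion collapses;
4. score apneas (≥ 90% nasal-pressure drop, 10–180 s, confirmed on a second
   flow channel) and split them into obstructive/central by the significance
   of RIP breathing attempts;
5. score hypopneas (≥ 30% airflow drop) and split them by snoring,
   thoracoabdominal paradox, or a flattened inspiratory shape (a 7-14-14-1
   sigmoid network);
6. build V̇<sub>cc</sub>, equilibrate per-cycle volumes, compute
   ΔP<sub>mus</sub> and P<sub>ch</sub>.

No public polygraph recording accompanies this pipeline, so the package
includes a first-class synthetic-night generator (`respibench.synth`) that
scripts normal breathing, all four event kinds, snoring, paradox, and
movement artifacts at the native channel rates, writes standard EDF, and
emits a ground-truth annotation track — every stage is tested against it.

## Worked example

```bash
respibench synth --duration 1800 --seed 7 --outdir demo/night
respibench process demo/night/night.edf --outdir demo/out
respibench bench demo/out --outdir demo/bench
respibench evaluate demo/out/preprocessed.csv demo/bench/bench_trace.csv --outdir demo/eval
```

The first three commands print:

```
wrote demo/night/night.edf (1800 s, 10 scripted events)
436 cycles, 10 events, 0.50 stable hours -> demo/out
replayed 436 cycles -> demo/bench/bench_trace.csv
```

`demo/out/events.json` summarizes the scored events per stable hour — here
AHI 20.0 (AI 12.0, HI 8.0), e.g. an obstructive apnea at 303.7 s lasting
14.7 s with 4 significant breathing attempts. The evaluation report
(`demo/eval/evaluation.json`) for this half-hour replay gives:

* relative amplitude bias **0.46 ± 7.00** percentage points per cycle —
  the bench reproduces each breath's relative depth essentially unbiased;
* total cycle time bias **0.029 ± 0.342 s** — cycle timing is preserved to
  a third of a second;
* per-cycle Pearson r **0.985 ± 0.089** for unobstructed cycles — waveform
  morphology is carried through the lung model nearly unchanged;
* apnea sensitivity and PPV **1.00 / 1.00** — every apnea scored in the
  recording reappears in the bench airflow, and nothing spurious does.

## Layout

```
src/respibench/
  io_polygraph.py   EDF reading, resampling, smoothing, airflow estimate
  stability.py      accelerometer-energy segmentation (adaptive threshold)
  ampd.py           multiscale peak detection
  breaths.py        cycle onsets, envelopes, reduced-excursion segments
  events.py         apnea/hypopnea scoring and obstructive/central typing
  commands.py       V'cc, volume equilibration, dP_mus, P_ch, calibration
  virtual_bench.py  lung + Starling-resistor surrogate
  evaluation.py     agreement statistics (bias, Bland-Altman, r, sens/PPV)
  synth.py          ground-truthed synthetic polygraph nights
  pipeline.py       orchestration; cli.py  command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
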