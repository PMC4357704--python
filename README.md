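# oritime

Analyses around DNA-replication-origin firing for three data modalities:

1. **Replication-timing-resolved ChIP enrichment** — given a smoothed
   Repli-Seq timing profile (1-kb intervals scored 0–100, higher = earlier)
   and read coverage for a histone mark and its input, the package counts
   reads per interval, normalizes by library size, sums the normalized
   coverage into 100 equal timing bins (reversed so bin 1 is the earliest),
   and compares mark vs input with a Kolmogorov–Smirnov test computed
   directly on the binned CDFs.
2. **DNA fiber combing** — dual-pulse (IdU 15 min, then CldU 30 min)
   labelled fibers are parsed into replication structures: fork velocity
   from CldU tracks of ongoing forks, inter-origin distances (IOD) between
   initiation events on the same fiber, and a five-class replication-figure
   census (isolated fork, one-origin bidirectional, single origin only,
   interspersed origins, termination), compared across conditions with
   Mann–Whitney and chi-square tests.
3. **Small quantifications** — ChIP-qPCR percent input, relative BrdU
   fluorescence from cytometry, and H3-normalized densitometry.

A synthetic-data generator (`oritime.synth`) produces genomes with early and
late origins, timing profiles, ChIP/input coverage, fiber sets under
configurable origin-firing efficiencies, Ct tables and cytometry draws, so
the whole pipeline is testable without external data.

Intended users: computational biologists analysing replication-timing /
ChIP / fiber-combing experiments, and anyone who wants a reproducible,
self-contained model of how an origin-firing deficit propagates into those
readouts.

## The statistics at the core

**Timing distributions.** For intervals *i* with timing value
*v<sub>i</sub>* ∈ [0,100] and read counts *c<sub>i</sub>* from a library of
size *N*, bin mass is

&nbsp;&nbsp;&nbsp;&nbsp;m(b) = Σ<sub>i∈b</sub> c<sub>i</sub>/N,&nbsp;&nbsp;
b = 1…100 (equal-width bins on [0,100], order reversed so b=1 is earliest).

**KS comparison.** With F̂<sub>A</sub>, F̂<sub>B</sub> the binned CDFs,
the one-sided statistic is D⁺ = max<sub>b</sub> (F̂<sub>A</sub>(b) −
F̂<sub>B</sub>(b)) and the p-value uses the asymptotic form
p = exp(−2 m D⁺²) with an assumed per-sample size n = 100 (m = n²/2n = 50);
two-sided p comes from the Kolmogorov series. A mark is called
*early-shifted* when D⁺(mark, input) > D⁺(input, mark).

**Combing.** Fork velocity = CldU track length / 30 min, measured only on
CldU tracks adjacent to an IdU track on exactly one side and not truncated
by a fiber end. An initiation event is an IdU core flanked by CldU on both
sides (or a divergent CldU-only pair across a sub-resolution gap); IODs are
distances between consecutive events on one fiber. Mann–Whitney U is exact
(full null enumeration) when there are no ties and n<sub>a</sub>·n<sub>b</sub> ≤ 400,
otherwise the tie-corrected normal approximation; the chi-square statistic
uses pooled expected counts.

**Percent input.** With the input Ct adjusted for the aliquot fraction,
% input = 100 · 2^(ct_input_adj − ct_IP).

## Worked example

```python
from oritime import synth, timing, combing

cfg = synth.chip_config(seed=1)                    # licensed-origin genome
genome = synth.make_genome(cfg, early_fraction=0.5)
profile = synth.make_timing_profile(genome, cfg)
d_mark = timing.timing_distribution(
    synth.make_chip_track(genome, "H3K4me3", cfg), profile)
d_input = timing.timing_distribution(
    synth.make_chip_track(genome, "input", cfg), profile)
print(timing.mark_vs_input_report({"H3K4me3": d_mark}, d_input))
```

prints

```
      mark         D   p_value direction  early_shift
0  H3K4me3  0.193551  0.023607     early         True
```

i.e. the H3K4me3 coverage distribution leads the input CDF by D⁺ = 0.19
across the timing bins — the mark is concentrated in early-replicating
DNA — and at the assumed n = 100 this shift is significant (p ≈ 0.024).

```python
cfg = synth.combing_config(seed=1, n_fibers=900)   # fiber experiment
genome = synth.make_genome(cfg, early_fraction=1.0,
                           conditions={"control": 1.0, "knockdown": 0.5})
for cond in ("control", "knockdown"):
    fibers = synth.make_fibers(genome, cond, cfg)
    v = [m.velocity for m in combing.fork_velocity(fibers)][:200]
    d = [m.distance for m in combing.inter_origin_distances(fibers)][:100]
    print(cond, combing.box_summary(v).median, combing.box_summary(d).median)
```

prints

```
control 1.5051632084157247 138.69782311930783
knockdown 1.5012332502306587 164.43414814777486
```

— halving the origin-firing probability leaves the median fork velocity at
~1.5 kb/min (no elongation defect) while the median inter-origin distance
grows from ~139 to ~164 kb (an initiation defect), the signature of an
origin-activation deficit.

A subcommand CLI wraps the same library:

```sh
oritime simulate   --config config.yaml --out sim/
oritime timing-dist --profile sim/timing_profile.bedgraph \
    --track H3K4me3 sim/coverage_H3K4me3.bedgraph \
    --track input   sim/coverage_input.bedgraph --out timing/
oritime combing    --fibers sim/fibers_control.tsv \
    --fibers-b sim/fibers_knockdown.tsv --out combing/
oritime qpcr       --ct sim/ct_table.csv --out qpcr/
```

Every run writes a `manifest.json` (parameters, version, input checksums);
two runs from the same manifest are byte-identical.

## Layout

- `src/oritime/synth.py` — synthetic genomes, timing, coverage, fibers,
  qPCR, cytometry
- `src/oritime/timing.py` — interval coverage, timing bins, KS comparison
- `src/oritime/combing.py` — events, velocity, IOD, figure classes, tests
- `src/oritime/quant.py` — % input, relative BrdU, densitometry
- `src/oritime/io.py`, `src/oritime/cli.py` — formats, manifest, CLI
- `docs/methods.md` — model description, parameter choices, limitations
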