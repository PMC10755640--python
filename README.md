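# forage

A simulator and analysis pipeline for the *dynamic foraging* task — the
two-port, baited-reward probabilistic reversal-learning paradigm used to
probe behavioral flexibility, motivation and choice strategy in mice
(e.g., in comparisons of *Scn2a* haploinsufficient animals against
wild-type littermates). The package is aimed at behavioral
neuroscientists who want a tested, reproducible software model of the
task's rules and of the full analysis battery, exercised entirely on
synthetic cohorts.

## The task and its statistics

On each trial an agent chooses the **left** or **right** port. Port *i*
carries reward probability *p_i*; with **baiting**, a reward assigned to a
port remains available until that port is next chosen, so the probability
a port pays off at first visit after *k* skipped trials is
1 − (1 − *p*)*^k* — the property that makes matching-like sampling of both
ports optimal. The implemented variants:

- **training (0/100)** — *p* = 1.0 vs 0.0; uncued reversals every 100
  trials *or* once 9 of the last 10 choices were to the high port;
- **full task (15/60)** — baited *p* = 0.60 vs 0.15, uncued reversal every
  80 trials (40- and 100-trial and mixed-contingency presets included);
- **head-fixed bandit (70:10)** — lick-based variant with truncated-
  exponential no-lick periods (rate 0.3333 s⁻¹ on [1, 5] s, at most 5
  draws, hence a 25 s ceiling), block switches armed by 10 high-side
  choices plus a truncated-geometric delay (μ = 11 on [0, 30] trials),
  and termination after 20 consecutive no-responses.

From trial logs the package computes learning curves, reversal-aligned
choice probability P(choose new high side | trial *k* after reversal),
win-stay/lose-switch fractions, outcome-conditional inter-trial-interval
(ITI) medians/IQRs, 10-trial moving-average choice traces and the
matching ratio *p_L*/(*p_L* + *p_R*). Groups are compared with a
mixed-design two-way ANOVA (between factor × repeated factor, subject
nested in group) and Bonferroni-corrected pairwise Mann–Whitney U tests
(exact enumeration for small tie-free samples; tie- and
continuity-corrected normal approximation otherwise), α = 0.05.

## Worked example

Simulate a null cohort (identical WT and HET agents, 12 subjects per
genotype × sex cell) and run the whole pipeline:

```bash
forage report -o demo/ --seed 1
```

`demo/report.md` then contains:

```
| metric | U | p | p (Bonferroni) | significant |
|---|---|---|---|---|
| iti_median_rewarded_s | 356.0 | 0.1640 | 0.6559 | no |
| iti_median_unrewarded_s | 368.0 | 0.1012 | 0.4046 | no |
| lose_switch | 273.0 | 0.7649 | 1.0000 | no |
| win_stay | 328.0 | 0.4154 | 1.0000 | no |

Conclusion: no genotype effect detected on any metric after Bonferroni correction.
```

Each row is one per-subject metric compared WT vs HET (24 subjects per
group): U is the rank statistic, p its two-sided Mann–Whitney p-value and
the adjusted column multiplies by the family size 4. Because the two
genotypes were generated with identical agent parameters, the correct
conclusion is exactly this null. Individual stages are also available as
`forage simulate`, `forage analyze` and `forage compare`, all reading and
writing plain CSV/JSON/YAML; the library API (`forage.run_session`,
`forage.generate_cohort`, `forage.reversal_aligned`, ...) exposes the same
functionality programmatically.

## Layout

- `src/forage/task_engine.py` — task rules, presets, session loop
- `src/forage/agents.py` — synthetic behaving agents and latency models
- `src/forage/cohort.py` — labeled multi-subject cohort generation
- `src/forage/metrics.py` — behavioral statistics
- `src/forage/stats.py` — mixed ANOVA, Mann–Whitney U, Bonferroni
- `src/forage/io.py`, `src/forage/cli.py` — CSV/YAML I/O, pipeline, CLI
- `docs/methods.md` — modeling assumptions and numerical conventions
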