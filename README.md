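# hanlon — Basic Priority Rating for health-program prioritization

`hanlon` is a validated scoring library and command-line tool for
priority-setting among public-health programs with the Hanlon method
family of Basic Priority Rating (BPR) equations. It is aimed at strategic
planners and public-health analysts who need a transparent, reproducible
way to turn expert panel ratings into a ranked, tiered program list —
the workflow national rater panels use when scoring both disease-oriented
programs (e.g. tuberculosis) and non-disease-oriented programs (e.g.
health-systems governance), with every program framed as a problem.

## The model

Each program receives component ratings:

| Component | Meaning | Range |
|---|---|---|
| A | size of the problem | 0–10 |
| B = B1+B2+B3+B4 | seriousness (urgency, severity, economic loss, negative impact on others; 0–5 each) | 0–20 |
| C = (C1/100)(C2/100)·10 | effectiveness (efficacy % × reach %), or a direct 0–10 rating | 0–10 |
| D | PEARL feasibility gate (product of 5 binary flags) | 0/1 |
| BC | benefit–cost rating | 0–10 |
| E | inequity between socially-determined sub-groups | 0–5 |
| F | institutional positioning multiplier (neutral = 1.00) | 0.67–1.50 |

and a BPR on the 0–100 scale under one of four equations:

```
original        BPR = (A + B) · C / 3 · D
Vilnius–Dandoy  BPR = (A + B) · (C + BC) / 6 · D
Neiger          BPR = (A + B) · C / 3          (PEARL as a pre-screen)
PAHO-adapted    BPR = (A + B + E) · C / 5.25 · F
```

Each divisor normalizes the maximal component product to 100 (e.g.
(10+20+5)·10·1.5 / 5.25 = 100). Multi-rater panels are aggregated by
per-component arithmetic means, programs are ordered by competition
ranking, and ranked lists are stratified into high/medium/low priority
tiers (rank tertiles by default, explicit BPR thresholds optionally).
Sensitivity tooling quantifies how rankings respond to the choice of
equation, to trial F ranges (the rejected 0.50–2.00 "halving to
doubling" range can be re-enacted), and to one-at-a-time component
perturbations, using Spearman's ρ and Kendall's τ-b on the rank vectors.
A synthetic rater-panel generator (truncated Gaussian rater noise around
a consensus, log-scale noise for F) supports validation and panel-size
experiments without any real country data.

## Worked example

The packaged fixture carries the mean component scores of a 12-country
pilot panel for three of the 24 catalog programs:

```sh
hanlon score "$(python -c 'import hanlon;print(hanlon.pilot_template_path())')" --method paho
```

prints

```
Program                                         BPR Rank  Tier
--------------------------------------------------------------
4.1 Health governance and financing; nat...    38.4    1  high
5.1 Alert and response capacities (for IHR)    37.7    2  medium
1.1 HIV/AIDS and STIs                          27.3    3  low
```

i.e. for program 1.1, BPR = (5.0 + 13.6 + 3.1) · 6.6 / 5.25 · 1.0 = 27.3:
the health-governance program outranks the two others, and with three
programs the rank tertiles place one program per tier. The same pipeline
is available as a library:

```python
import hanlon as h

panel = h.pilot_consensus_panel()            # 12 identical rater sheets
for r in h.score_panel(panel, "paho"):
    print(r.program.id, round(r.bpr.value, 1), r.rank, r.tier)
# 4.1 38.4 1 high
# 5.1 37.7 2 medium
# 1.1 27.3 3 low
```

The CLI also offers `validate` (template checking), `screen` (PEARL
pre-filter), `simulate` (synthetic panels from a YAML scenario) and
`sensitivity` (method/F-range/perturbation reports); see `hanlon --help`.

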