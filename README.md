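# mcqkit

Scoring and missing-response imputation for the 21- and 27-item Monetary
Choice Questionnaire (MCQ), plus a Monte Carlo harness for evaluating the
imputation approaches and a synthetic-cohort generator with known true
discount rates.

The MCQ is a battery of binary choices between a smaller-immediate and a
larger-delayed monetary reward. Each item corresponds to a discount rate
`k = (A/V − 1)/D` of the hyperbolic model `V = A/(1 + kD)`; an individual's
rate is estimated from the switch point of their choice pattern via
consistency scores, yielding five estimates (overall, small, medium, large
and composite `k`). `mcqkit` implements that scorer together with four ways
of handling missing responses:

| method       | idea                                                              |
|--------------|-------------------------------------------------------------------|
| `mode`       | fill each missing cell with the per-item mode                     |
| `ggm`        | no fill; composite `k` from whichever amount sets are complete    |
| `inn`        | copy congruent same-`k`-rank responses from the other amount sets |
| `inn-random` | as `inn`, then fair random fills for anything still missing       |

## CLI

```sh
# complete synthetic cohort with known true ln k and a correlated covariate
mcq synth --bank 21 --n 900 --seed 7 --out responses.csv --truth truth.csv

# strict scoring (complete rows only get a composite k)
mcq score --bank 21 --in responses.csv --out scores.csv

# impute missing responses, score, and log every fill with its provenance
mcq impute --method inn-random --bank 21 --seed 7 \
    --in responses.csv --out scores.csv --report fills.csv

# Monte Carlo evaluation of all four approaches (r missing per respondent)
mcq simulate --bank 27 --r 1-7 --iters 1000 --seed 7 \
    --out metrics.csv --table table.csv --archive iterations.csv
```

Every subcommand also takes `--config file.yaml` (explicit flags win), and
writes a deterministic run manifest next to its output; reruns with the
same seed are byte-identical.

Response CSVs are wide: `respondent_id,item_1,…,item_n` with cells `0`
(immediate), `1` (delayed) or empty/`NA` (missing).

## Python API

```python
import numpy as np
from mcqkit import (load_packaged_bank, default_config, generate_cohort,
                    apply_approach, inject_missing)

bank = load_packaged_bank(27)
matrix, truth = generate_cohort(bank, default_config(bank, seed=1))
degraded = inject_missing(matrix, r=3, rng=np.random.default_rng(2))
scores, report = apply_approach(degraded, bank, "ggm")
print(report.unimputable_respondents)          # rows with no composite k
```

`expected_ggm_failures(n, m, r)` gives the closed-form expectation of that
count (inclusion–exclusion over the three amount sets), which the Monte
Carlo results converge to.

## Layout

- `src/mcqkit/item_bank.py` — item tables, validation, `k` computation/ordering
- `src/mcqkit/scorer.py` — consistency-score rate estimation
- `src/mcqkit/imputation.py` — the four approaches and fill reports
- `src/mcqkit/synthetic.py` — cohort generator and MCAR removal
- `src/mcqkit/harness.py` — Monte Carlo study, metrics, analytic GGM oracle
- `src/mcqkit/io.py`, `src/mcqkit/cli.py` — CSV formats and the `mcq` CLI
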