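#!/usr/bin/env python
"""Mortality analyses: KM by methylation quartile, log-rank, Cox models 1-3
for the methylation score (all-cause + cause-specific), penalised selection."""

from pathlib import Path

import pandas as pd

from methrisk.config import CPG_SITES, SCORE_CPGS
from methrisk.cox import fit_cox
from methrisk.km import logrank
from methrisk.models import cause_specific_events, cox_design
from methrisk.penalized import fit_penalized_cox
from methrisk.score import assign_quartiles, build_score
from methrisk.simulate import read_cohort

DATA = Path("results/data")
OUT = Path("results")


def main():
    d = read_cohort(DATA)
    times = d.survival["time"].to_numpy(float)
    events = d.survival["event"].to_numpy(int)
    qa = assign_quartiles(d.methylation)
    score = build_score(qa)["score"]

    chi2, df, p = logrank(times, events, qa.quartiles["cg05575921"])
    print(f"log-rank across cg05575921 quartiles: chi2={chi2:.1f} "
          f"(df={df}), p={p:.2g}")

    rows = []
    for cause in ("all", "CVD", "cancer", "other"):
        ev = cause_specific_events(d.survival, cause)
        for model in (1, 2, 3):
            design = cox_design(d.cohort, model=model, score=score,
                                smoking=model >= 2)
            fit = fit_cox(times, ev, design)
            if model >= 2:
                summ = fit.summary().loc[["score[1]", "score[2]"]]
                summ = summ.reset_index(names="term")
                summ.insert(0, "cause", cause)
                summ.insert(1, "model", model)
                rows.append(summ)
    tab = pd.concat(rows, ignore_index=True)
    tab.to_csv(OUT / "table3_cox_score.csv", index=False)
    m3 = tab[tab["model"] == 3].set_index(["cause", "term"])
    print("\nmodel-3 HRs for methylation score 2 vs 0:")
    for cause in ("all", "CVD", "cancer", "other"):
        r = m3.loc[(cause, "score[2]")]
        print(f"  {cause:>6}: HR {r['hr']:.2f} ({r['hr_low']:.2f}, "
              f"{r['hr_high']:.2f})")

    meth = d.methylation[list(CPG_SITES)]
    meth = meth.fillna(meth.mean())
    design = pd.concat([meth, pd.DataFrame({
        "age": d.cohort["age"].astype(float),
        "male": (d.cohort["sex"] == "male").astype(float)})], axis=1)
    path = fit_penalized_cox(times, events, design,
                             penalized_cols=list(CPG_SITES), seed=1)
    print(f"\nL1-penalised Cox selected CpGs: {path.selected} "
          f"(lambda={path.best_lambda:.3g})")
    print(f"the two score CpGs {list(SCORE_CPGS)} "
          f"{'are' if set(SCORE_CPGS) <= set(path.selected) else 'are NOT'} "
          f"among them")


if __name__ == "__main__":
    main()
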