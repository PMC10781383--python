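"""Fit PLSR and SVR on selected subsets and validate with LOOCV.

Compares both model families across preprocessing arms and SFS-selected
subsets (plus the full 32-variable set), mirroring a model-comparison
table: R^2 and RMSE per model x target x arm.  Writes the comparison table
and measured-vs-predicted scatter plots under results/models/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import leafspec as ls

OUT = Path("results/models")
SEED = 20230217


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    from importlib import import_module
    build_tables = import_module("05_select_variables").build_tables
    tables = build_tables()

    rows = []
    scatter = {}
    for arm, table in tables.items():
        for target in ("chl_ab", "car"):
            subsets = {"all": None}
            sel_lm = ls.sfs_select(table, target,
                                   ls.LearnerSpec(kind="lm", seed=SEED))
            sel_svm = ls.sfs_select(table, target,
                                    ls.LearnerSpec(kind="svm_rbf", seed=SEED,
                                                   tuning="tune_once"))
            subsets["lm-sfs"] = sel_lm.subset
            subsets["svm-sfs"] = sel_svm.subset
            for sel_name, subset in subsets.items():
                for family in ("plsr", "svr_rbf"):
                    rep = ls.loocv(ls.ModelSpec(family=family, seed=SEED),
                                   table, target, subset)
                    rows.append({"arm": arm, "target": target,
                                 "selection": sel_name, "model": family,
                                 "n_vars": len(rep.subset),
                                 "r2": round(rep.r2, 4),
                                 "rmse": round(rep.rmse, 4)})
                    scatter[(arm, target, sel_name, family)] = rep
                    print(f"{arm:3s} {target:6s} {sel_name:7s} {family:7s} "
                          f"R2={rep.r2:.4f} RMSE={rep.rmse:.4f}")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "model_comparison.csv", index=False)

    # headline scatter plots: PLSR + lm-sfs on OS vs SVR + svm-sfs on MSC
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    picks = [("os", "plsr", "lm-sfs"), ("msc", "svr_rbf", "svm-sfs")]
    for j, (arm, family, sel_name) in enumerate(picks):
        for i, target in enumerate(("chl_ab", "car")):
            rep = scatter[(arm, target, sel_name, family)]
            ax = axes[i][j]
            ax.scatter(rep.predictions["measured"], rep.predictions["predicted"],
                       s=18, alpha=0.8)
            lims = [rep.predictions.min().min(), rep.predictions.max().max()]
            ax.plot(lims, lims, "k--", lw=0.8)
            ax.set_title(f"{family} + {sel_name} ({arm.upper()}) {target}\n"
                         f"R$^2$={rep.r2:.3f} RMSE={rep.rmse:.3f}")
            ax.set_xlabel("measured (ug/cm$^2$)")
            ax.set_ylabel("LOOCV predicted")
    fig.tight_layout()
    fig.savefig(OUT / "scatter_measured_vs_predicted.png", dpi=120)
    print(f"wrote {OUT}/model_comparison.csv and scatter plots")


if __name__ == "__main__":
    main()
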