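"""Run the three variable-selection algorithms on both preprocessing arms.

CORR (with PLS and SVM learners), SFS and RFE (with LM and SVM learners)
are applied to the 32-variable table for Chl_a+b and Car, on original (OS)
and MSC-corrected spectra.  Writes each SelectionResult as JSON, a summary
table, and the CORR RMSE-curve figure under results/selection/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import leafspec as ls

OUT = Path("results/selection")
SEED = 20230217


def build_tables():
    cfg = ls.SceneConfig()
    img, gt = ls.render_scene(cfg)
    cal = ls.calibrate(img, cfg.panel_region, cfg.panel_reflectance)
    leaves = ls.segment_leaves(cal, exclude_region=cfg.panel_region)
    _, _, aligned = ls.match_labels(leaves, gt.label_map, gt.table)
    ideal = ls.ideal_spectrum(leaves, cal)
    corrected = ls.msc_correct(leaves.spectra, ideal)
    return {"os": ls.normalize(ls.build_feature_table(leaves.spectra, aligned)),
            "msc": ls.normalize(ls.build_feature_table(corrected, aligned))}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = build_tables()
    # the study's algorithm/learner pairings; tune-once grids keep the SVM
    # wrapper searches tractable on one core
    runs = [("corr", "pls"), ("corr", "svm_rbf"),
            ("sfs", "lm"), ("sfs", "svm_rbf"),
            ("rfe", "lm"), ("rfe", "svm_rbf")]
    rows = []
    curves = {}
    for arm, table in tables.items():
        for target in ("chl_ab", "car"):
            for algo, learner in runs:
                spec = ls.LearnerSpec(kind=learner, seed=SEED, tuning="tune_once")
                fn = {"corr": ls.corr_select, "sfs": ls.sfs_select,
                      "rfe": ls.rfe_select}[algo]
                res = fn(table, target, spec)
                res.to_json(OUT / f"{algo}_{learner}_{arm}_{target}.json")
                rows.append({"arm": arm, "target": target, "algorithm": algo,
                             "learner": learner, "n_vars": len(res.subset),
                             "rmse": round(res.curve[res.chosen_step], 4),
                             "subset": " ".join(res.subset)})
                if algo == "corr":
                    curves[(arm, target, learner)] = res.curve
                print(f"{arm:3s} {target:6s} {algo}-{learner}: "
                      f"{len(res.subset)} vars, RMSE {res.curve[res.chosen_step]:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "selection_summary.csv", index=False)

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for j, target in enumerate(("chl_ab", "car")):
        for i, arm in enumerate(("os", "msc")):
            ax = axes[i][j]
            for learner in ("pls", "svm_rbf"):
                c = curves[(arm, target, learner)]
                ax.plot(range(1, len(c) + 1), c, marker=".", label=learner)
                ax.axvline(int(pd.Series(c).idxmin()) + 1, ls=":", lw=0.8)
            ax.set_title(f"CORR {target} ({arm.upper()})")
            ax.set_xlabel("number of variables")
            ax.set_ylabel("CV RMSE")
            ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "corr_rmse_curves.png", dpi=120)
    print(f"wrote {OUT}/selection_summary.csv and corr_rmse_curves.png")


if __name__ == "__main__":
    main()
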