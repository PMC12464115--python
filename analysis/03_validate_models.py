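"""Validate the winning cue-response-bias model (M3).

Runs the three-part validation battery: parameter recovery under the
cohort hyperdistribution, model recovery across all six candidates, and a
posterior predictive check of condition-wise go-rate learning curves at the
fitted parameters. Writes results/validation.json and a PPC figure.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from itpav.cohort import CohortConfig, CohortData, sample_params
from itpav.models import MODELS, ModelParams
from itpav.task import generate_schedule
from itpav.validation import model_recovery, parameter_recovery, posterior_predictive


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--fits", default="results/fits.csv")
    ap.add_argument("--out", default="results")
    ap.add_argument("--n-recovery", type=int, default=30)
    ap.add_argument("--n-per-model", type=int, default=5)
    ap.add_argument("--ppc-sims", type=int, default=20)
    args = ap.parse_args()

    spec = MODELS["M3"]
    schedule = generate_schedule(50, 2, 0.8, seed=args.seed)

    pp = sample_params(CohortConfig(n_participants=args.n_recovery),
                       seed=args.seed + 1)
    truths = [ModelParams(alpha=pp.alpha[i], tau=pp.tau[i], xi=pp.xi[i],
                          b=pp.b[i], pi=pp.pi[i]).resolved(spec)
              for i in range(args.n_recovery)]
    recovery = parameter_recovery(spec, args.n_recovery, schedule,
                                  seed=args.seed + 2, truths=truths)
    print("parameter recovery (true vs recovered r):")
    for name, r in sorted(recovery.correlation.items()):
        print(f"  {name:5s} r = {r:.3f}  bias = {recovery.bias[name]:+.3f}")

    confusion = model_recovery(list(MODELS.values()), args.n_per_model,
                               schedule, seed=args.seed + 3,
                               ranges=dict(pi=(0.5, 1.2), b=(-0.5, 0.5),
                                           xi=(0.0, 0.25), tau=(4.0, 12.0)))
    print("\nmodel recovery confusion matrix (rows: generating model):")
    print(confusion.round(2).to_string())

    report = dict(
        parameter_recovery=dict(correlation=recovery.correlation,
                                bias=recovery.bias, rmse=recovery.rmse),
        model_recovery=confusion.round(4).to_dict(),
    )

    fits_path = Path(args.fits)
    if fits_path.exists():
        cohort = CohortData.read(args.cohort)
        fits = pd.read_csv(fits_path)
        win = fits[fits["model"] == "M3"].set_index("participant_id")
        sessions = cohort.sessions()
        ids = list(sessions)[:20]
        pairs = [(ModelParams(alpha=win.loc[i, "alpha"],
                              tau=win.loc[i, "tau"], xi=win.loc[i, "xi"],
                              b=win.loc[i, "b"],
                              pi=win.loc[i, "pi"]).resolved(spec), spec)
                 for i in ids]
        ppc = posterior_predictive(pairs, [sessions[i] for i in ids],
                                   schedule, n_sims=args.ppc_sims,
                                   seed=args.seed + 4)
        print(f"\nposterior predictive: {ppc.coverage:.0%} of trial bins "
              f"inside the {ppc.n_sims}-replicate band")
        report["posterior_predictive"] = dict(
            coverage=ppc.coverage,
            discrepancy=ppc.discrepancy.round(4).to_dict())
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
            for ax, cond in zip(axes.ravel(), ppc.observed.index):
                x = ppc.observed.columns.to_numpy()
                ax.plot(x, ppc.observed.loc[cond], "k.-", lw=1,
                        label="observed")
                ax.plot(x, ppc.simulated_mean.loc[cond], "C0-",
                        label="simulated")
                ax.fill_between(x, ppc.simulated_lo.loc[cond],
                                ppc.simulated_hi.loc[cond], color="C0",
                                alpha=0.25)
                ax.set_title(cond)
                ax.set_ylim(0, 1)
            axes[0, 0].legend(frameon=False)
            fig.supxlabel("cue presentation")
            fig.supylabel("p(go)")
            fig.tight_layout()
            fig.savefig(Path(args.out) / "ppc_learning_curves.png", dpi=120)
            print(f"PPC figure -> {args.out}/ppc_learning_curves.png")
        except ImportError:
            pass

    Path(args.out).mkdir(parents=True, exist_ok=True)
    (Path(args.out) / "validation.json").write_text(
        json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
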