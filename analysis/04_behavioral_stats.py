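"""Hierarchical behavioural statistics on the simulated cohort.

Estimates the Pavlovian response bias (hierarchical logistic) and RT bias
(hierarchical shifted-lognormal), scans all mental-health covariates for
moderation of the reward effect with BH correction, and correlates
impatience scores and the fitted cue-response bias with the covariates.
Writes effect and correlation tables under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from itpav.cohort import CohortData
from itpav.stats import (build_design, correlate_with_mh, fit_response_bias,
                         fit_rt_bias, moderation_scan)


def show(tag: str, est: pd.DataFrame) -> None:
    print(f"\n{tag} (sum-to-zero coded):")
    for _, r in est.iterrows():
        star = " *" if r["significant"] else ""
        print(f"  {r['effect']:22s} b = {r['mean']:+.3f} "
              f"[{r['lower']:+.3f}, {r['upper']:+.3f}]{star}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--fits", default="results/fits.csv")
    ap.add_argument("--out", default="results")
    ap.add_argument("--q", type=float, default=0.05)
    args = ap.parse_args()

    cohort = CohortData.read(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    design = build_design(cohort.trials)

    response = fit_response_bias(design)
    response.to_csv(out / "response_bias.csv", index=False)
    show("response bias (log-odds of go)", response)

    rt = fit_rt_bias(design)
    rt.to_csv(out / "rt_bias.csv", index=False)
    show("RT bias (log ms, go responses)", rt)

    scan = moderation_scan(cohort.trials, cohort.mental_health, "response",
                           args.q)
    scan["primary"].to_csv(out / "moderation_primary.csv", index=False)
    scan["effects"].to_csv(out / "moderation_effects.csv", index=False)
    n_disc = int(scan["primary"]["bh_significant"].sum())
    print(f"\nmoderation scan: {len(scan['primary'])} covariates, "
          f"{n_disc} BH discoveries on the reward x covariate term "
          f"(q = {args.q})")

    impatience = cohort.titration.set_index("participant_id")["impatience"]
    corr_imp = correlate_with_mh(impatience, cohort.mental_health, args.q)
    corr_imp.to_csv(out / "impatience_correlations.csv", index=False)
    print(f"impatience correlations: max |r| = "
          f"{corr_imp['r'].abs().max():.3f}, "
          f"{int(corr_imp['bh_significant'].sum())} BH discoveries")

    fits_path = Path(args.fits)
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        pi_hat = fits[fits["model"] == "M3"].set_index(
            "participant_id")["pi"]
        corr_pi = correlate_with_mh(pi_hat, cohort.mental_health, args.q)
        corr_pi.to_csv(out / "pi_correlations.csv", index=False)
        print(f"cue-response bias correlations: max |r| = "
              f"{corr_pi['r'].abs().max():.3f}, "
              f"{int(corr_pi['bh_significant'].sum())} BH discoveries")


if __name__ == "__main__":
    main()
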