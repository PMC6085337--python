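"""Trait associations in the mutualistic metawebs (RLQ + fourth corner).

For each mutualism: builds the binary metaweb, fits the degree-weighted
RLQ ordination of plant and animal traits, selects the axes covering
99% of the cross-covariance, tests the global association (sum of
eigenvalues, fourth-corner model 6) and the per-axis score correlations,
and finally aggregates per-trait-type significance across mutualisms
with Moran's exact Bernoulli probability.

Reads the bundle written by 01_simulate_dataset.py; writes tables under
results/trait_associations/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mutualinet import core_data
from mutualinet._utils import spawn_seed
from mutualinet.rlq_fourthcorner import (
    moran_probability,
    permutation_test,
    rlq,
    select_axes,
    trait_axis_correlations,
    trait_type_summary,
)


def load_bundle(data_dir: Path):
    def traits(name, level):
        meta = pd.read_csv(data_dir / f"{name}_meta.csv")
        return core_data.read_trait_table(
            data_dir / f"{name}.csv", dict(zip(meta["trait"], meta["trait_type"])), level
        )

    return (
        traits("plant_traits", "plant"),
        traits("animal_traits", "animal"),
        core_data.read_interactions(data_dir / "interactions.csv"),
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/trait_associations"))
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plants, animals, interactions = load_bundle(args.data)
    plants_t = core_data.sqrt_transform(plants)
    animals_t = core_data.sqrt_transform(animals)

    eig_rows, corr_frames, pvals = [], [], {}
    for i, mutualism in enumerate(sorted(interactions.records["mutualism"].unique())):
        L = interactions.metaweb(mutualism)
        fit = rlq(plants_t, L, animals_t)
        k = select_axes(fit, 0.99)
        test = permutation_test(
            plants_t, L, animals_t, "sum_eigenvalues",
            n_perm=args.n_perm, model=6, seed=args.seed + i,
        )
        ax_tests = {
            ax: permutation_test(
                plants_t, L, animals_t, "axis_correlation",
                n_perm=args.n_perm, model=6, seed=args.seed + 10 * i + ax, axis=ax,
            )
            for ax in (1, 2)
        }
        print(
            f"{mutualism}: metaweb {L.shape[0]}x{L.shape[1]}, "
            f"sum(lambda) = {fit.eigenvalues.sum():.3f} (model-6 P = {test.p_model6:.4f}); "
            f"axes kept = {k} ({fit.percent_covariance[:k].round(1)}% of cross-covariance); "
            f"axis-1 score correlation r = {ax_tests[1].observed:.2f} (P = {ax_tests[1].p_model6:.4f})"
        )
        for j in range(fit.k):
            eig_rows.append(
                {
                    "mutualism": mutualism,
                    "axis": j + 1,
                    "eigenvalue": fit.eigenvalues[j],
                    "pct_cross_covariance": fit.percent_covariance[j],
                    "selected": j < k,
                }
            )
        corr = trait_axis_correlations(fit, plants_t, animals_t)
        corr.insert(0, "mutualism", mutualism)
        corr_frames.append(corr)
        pvals[mutualism] = {
            "sum_eigenvalues": {"observed": test.observed, "p_model6": test.p_model6},
            "axis_correlations": {
                str(ax): {"r": t.observed, "p_model6": t.p_model6} for ax, t in ax_tests.items()
            },
        }

    pd.DataFrame(eig_rows).to_csv(args.out / "eigenvalues.csv", index=False)
    corr_all = pd.concat(corr_frames, ignore_index=True)
    corr_all.to_csv(args.out / "trait_axis_correlations.csv", index=False)
    summary = trait_type_summary(corr_all, axis=1)
    summary.to_csv(args.out / "trait_type_summary_axis1.csv", index=False)

    # Moran aggregation: per trait type, how many per-mutualism trait-axis
    # tests on axis 1 are individually significant, vs. chance expectation
    moran = {}
    for ttype in ("matching", "energy", "foraging"):
        sub = corr_all[(corr_all.trait_type == ttype) & (corr_all.axis == 1)]
        n_tests, n_sig = 0, 0
        for _, row in sub.iterrows():
            mutualism = row["mutualism"]
            L = interactions.metaweb(mutualism)
            t = permutation_test(
                plants_t, L, animals_t, "trait_axis_correlation",
                n_perm=args.n_perm, model=6,
                seed=spawn_seed(args.seed, ttype, row["trait"], mutualism),
                axis=1, trait=row["trait"], trait_level=row["level"],
            )
            n_tests += 1
            n_sig += t.p_model6 <= 0.05
        moran[ttype] = {
            "n_tests": n_tests,
            "n_significant": n_sig,
            "moran_P": moran_probability(n_tests, n_sig, 0.05),
        }
        print(
            f"trait type {ttype!r}: {n_sig}/{n_tests} axis-1 tests significant, "
            f"Moran P = {moran[ttype]['moran_P']:.2e}"
        )
    (args.out / "fourthcorner_tests.json").write_text(
        json.dumps({"per_mutualism": pvals, "moran_by_trait_type": moran}, indent=2, default=float)
    )
    print(f"\ntables written to {args.out}")


if __name__ == "__main__":
    main()
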