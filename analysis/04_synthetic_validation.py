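"""Ground-truth validation of every pipeline stage on synthetic data.

Simulates the study's scale (9 compounds × 9 isotypes × 7 cell lines,
logIC50 linear in BE_w with noise 0.1, censoring at 100 µM) and checks:
slope recovery within sampling error per cell line, exact weight recovery
on noiseless weighted columns, residuals ≤ 0.02 kcal/mol after 2-decimal
rounding, and the null-model mean R² ≈ 1/(n−1).
"""

from pathlib import Path

import numpy as np
import statsmodels.api as sm

import isobind as ib

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = ib.make_truth(n_compounds=9, noise_sd=0.1, seed=SEED)
    potencies = ib.gen_potency(truth)
    bw = truth.weighted

    rows = []
    for line in bw.cell_line_ids:
        logs, excluded = ib.log_transform(potencies, line)
        shared = [c for c in bw.compound_ids if c in logs]
        x = np.array([dict(zip(bw.compound_ids, bw.column(line)))[c] for c in shared])
        y = np.array([logs[c] for c in shared])
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rec = ib.recover_weights(truth.matrix, bw.column(line))
        rounded = ib.recover_weights(
            ib.IsotypeBindingMatrix(
                list(truth.matrix.compound_ids),
                list(truth.matrix.isotype_ids),
                np.round(truth.matrix.energies, 2),
            ),
            np.round(bw.column(line), 2),
        )
        rows.append(
            {
                "cell_line": line,
                "slope_hat": fit.params[1],
                "slope_se": fit.bse[1],
                "slope_z": (fit.params[1] - truth.slope) / fit.bse[1],
                "n_used": len(shared),
                "n_censored": len(excluded),
                "weight_residual_rms": rec.residual_rms,
                "rounded_residual_max": rounded.residual_max,
            }
        )
    import pandas as pd

    df = pd.DataFrame(rows).set_index("cell_line")
    df.to_csv(RESULTS / "synthetic_validation.tsv", sep="\t", float_format="%.5f")
    print(df.round(4).to_string())
    assert (df["slope_z"].abs() <= 3).all()
    assert (df["weight_residual_rms"] <= 1e-6).all()
    assert (df["rounded_residual_max"] <= 0.02).all()
    print(f"\ntrue slope {truth.slope}: recovered within 3 SE in all "
          f"{len(df)} cell lines; weight recovery exact to 1e-6 unrounded "
          "and within 0.02 kcal/mol at printed precision.")

    # null calibration: slope 0, mean R² should be 1/(n−1) = 0.125
    n, reps = 9, 10_000
    rng = np.random.default_rng(SEED)
    null = ib.make_truth(n_compounds=n, n_lines=1, slope=0.0, intercept=0.0,
                         noise_sd=0.3, seed=SEED)
    x = null.weighted.values[:, 0]
    dx = x - x.mean()
    r2 = np.empty(reps)
    for k in range(reps):
        null.seed = int(rng.integers(2**31 - 1))
        pot = ib.gen_potency(null)
        y = np.log10([pot.entries[(c, "L1")][0] for c in null.matrix.compound_ids])
        dy = y - y.mean()
        r2[k] = (dx @ dy) ** 2 / ((dx @ dx) * (dy @ dy))
    print(f"null-model mean R² over {reps} replicates: {r2.mean():.4f} "
          f"(expected 1/(n−1) = {1 / (n - 1):.4f})")


if __name__ == "__main__":
    main()
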