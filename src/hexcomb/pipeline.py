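"""End-to-end orchestration: simulate or import, code features, fit, test.

The report bundle is plain data (dicts / DataFrames serialised to JSON and
CSV): per-variant mixture fits in a side-by-side table, the three inference
procedures, and histogram-with-fit data series in place of figures, so every
"figure" is testable.  Every stochastic stage records its seed, and the
report echoes the configuration and a hash of the input data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .board import build_board
from .cohort import BehaviourParams, CohortSpec, leadership_presets, simulate_cohort
from .features import features_table, summary_statistics
from .game import read_game_logs, replay_and_validate
from .mixture import (
    DEFAULT_TRIALS, FitConfig, MixtureFit, compare_models, design_matrix,
    fit_mixture, mixture_pmf,
)
from .resampling import exact_binomial_test, mclachlan_lrt, two_stage_bootstrap

log = logging.getLogger("hexcomb")

#: The model variants fitted side by side: mixing-weight covariates per name.
MODEL_VARIANTS: dict = {
    "empty": (),
    "local": ("local",),
    "first": ("first",),
    "first_local": ("first", "local", "first_x_local"),
    "consistency": ("same", "direction"),
}

_CANONICAL_COLUMNS = [
    "group_id", "arrivals", "local", "first", "same", "direction",
    "informed_mean_start_rank", "path_similarity", "informed_mean_path_length",
    "informed_mean_latency",
]
_MINIMAL_COLUMNS = ["group_id", "arrivals", "local", "first", "same", "direction"]


class FeatureSchemaError(ValueError):
    """Imported features violate the schema; the message lists row errors."""


def import_features(path, dialect: str = "auto") -> pd.DataFrame:
    """Read and validate a features CSV.

    ``dialect="canonical"`` expects the full schema written by
    :func:`hexcomb.features.features_table`; ``"minimal"`` accepts the
    six-column table (group_id, arrivals, local, first, same, direction)
    that a hand-converted copy of the original study's spreadsheet provides,
    with the control columns marked missing; ``"auto"`` picks by the columns
    present.
    """
    df = pd.read_csv(path)
    if dialect == "auto":
        dialect = "canonical" if set(_CANONICAL_COLUMNS) <= set(df.columns) else "minimal"
    required = _CANONICAL_COLUMNS if dialect == "canonical" else _MINIMAL_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FeatureSchemaError(f"missing columns {missing} for dialect {dialect!r}")

    errors = []
    for i, row in df.iterrows():
        if not 0 <= row["arrivals"] <= 8:
            errors.append(f"row {i}: arrivals={row['arrivals']} outside 0..8")
        for c in ("local", "first", "same", "direction"):
            if row[c] not in (0, 1):
                errors.append(f"row {i}: {c}={row[c]} not a 0/1 dummy")
        if row.get("same", 0) + row.get("direction", 0) > 1:
            errors.append(f"row {i}: same and direction both 1")
    if df["group_id"].duplicated().any():
        errors.append("duplicate group ids")
    if errors:
        raise FeatureSchemaError("; ".join(errors))
    for c in _CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df


def fit_variants(features: pd.DataFrame, variants: dict | None = None,
                 config: FitConfig | None = None) -> dict:
    """Fit each model variant whose covariates are available in the data."""
    variants = variants if variants is not None else MODEL_VARIANTS
    fits: dict = {}
    for name, covs in variants.items():
        needed = {c for c in covs if c != "first_x_local"}
        if "first_x_local" in covs:
            needed |= {"first", "local"}
        if any(c not in features.columns or features[c].isna().any()
               for c in needed):
            log.warning("variant %s skipped: covariates unavailable", name)
            continue
        fits[name] = fit_mixture(features, covs, config=config)
    return fits


def table2_style(fits: dict) -> pd.DataFrame:
    """Side-by-side rendering of the fitted variants (rows = parameters)."""
    all_betas: list = []
    for f in fits.values():
        for b in f.beta_names:
            if b not in all_betas:
                all_betas.append(b)
    rows = []
    for label in (["pi1", "pi2"] + all_betas
                  + ["neg_loglik", "p", "AIC", "BIC"]):
        row = {"parameter": label}
        for name, f in fits.items():
            if label == "pi1":
                v = f"{f.pi1:.3f}"
            elif label == "pi2":
                v = f"{f.pi2:.3f}"
            elif label in f.beta_names:
                i = f.beta_names.index(label)
                z = f.z_values[i] if f.z_values is not None else np.nan
                v = f"{f.beta[i]:.3f} (z={z:.3f})"
                if f.capped is not None and f.capped[i]:
                    v += " [capped]"
            elif label == "neg_loglik":
                v = f"{f.neg_loglik:.2f}"
            elif label == "p":
                v = str(f.n_params)
            elif label == "AIC":
                v = f"{f.aic:.2f}"
            elif label == "BIC":
                v = f"{f.bic:.2f}"
            else:
                v = "-"
            row[name] = v
        rows.append(row)
    return pd.DataFrame(rows)


def histogram_series(features: pd.DataFrame, fit: MixtureFit,
                     covariates=()) -> pd.DataFrame:
    """Histogram of arrivals with the fitted pmf and component contributions.

    Emitted as a data series (bin, observed count, fitted expected count and
    the two weighted component pmfs averaged over the design), the testable
    stand-in for the published histogram figures.
    """
    y = features["arrivals"].to_numpy(int)
    X, _ = design_matrix(features, covariates)
    alphas = fit.alpha(X)
    bins = np.arange(fit.trials + 1)
    from scipy.stats import binom as _binom
    comp1 = np.mean(alphas[:, None] * _binom.pmf(bins[None, :], fit.trials, fit.pi1), axis=0)
    comp2 = np.mean((1 - alphas)[:, None] * _binom.pmf(bins[None, :], fit.trials, fit.pi2), axis=0)
    counts = np.bincount(y, minlength=fit.trials + 1)
    return pd.DataFrame({
        "arrivals": bins,
        "count": counts,
        "fitted_count": len(y) * (comp1 + comp2),
        "component_low": comp1,
        "component_high": comp2,
    })


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus analysis settings."""

    preset: str | None = None           # simulate this behaviour preset ...
    game_logs: str | None = None        # ... or ingest a JSONL log file ...
    features_csv: str | None = None     # ... or load a features CSV ...
    use_reference: bool = False         # ... or the packaged synthetic cohort
    n_groups: int = 40
    n_local: int = 20
    seed: int = 0
    reps: int = 1000
    lrt_bootstrap: int = 200
    variants: tuple = tuple(MODEL_VARIANTS)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        sources = [self.preset is not None, self.game_logs is not None,
                   self.features_csv is not None, self.use_reference]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be set")


def _player_indicator_table(features: pd.DataFrame) -> np.ndarray:
    y = features["arrivals"].to_numpy(int)
    n = int(features["n_uninformed"].fillna(8).max()) if "n_uninformed" in features else 8
    table = np.zeros((len(y), n), dtype=int)
    for i, k in enumerate(y):
        table[i, :k] = 1
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    t0 = time.time()
    stage = "input"
    try:
        if config.preset is not None:
            params = leadership_presets(config.preset)
            spec = CohortSpec(n_groups=config.n_groups, n_local=config.n_local,
                              params=params, master_seed=config.seed)
            cohort = simulate_cohort(spec)
            stage = "validate"
            for g in cohort:
                replay_and_validate(g)
            stage = "features"
            features = features_table(cohort)
            source = f"simulate:{config.preset}"
        elif config.game_logs is not None:
            cohort = read_game_logs(config.game_logs)
            stage = "validate"
            for g in cohort:
                replay_and_validate(g)
            stage = "features"
            features = features_table(cohort)
            source = f"logs:{config.game_logs}"
        elif config.features_csv is not None:
            features = import_features(config.features_csv)
            source = f"csv:{config.features_csv}"
        else:
            features = datasets.reference_cohort()
            source = "reference"

        data_hash = hashlib.md5(
            features["arrivals"].to_numpy(np.int64).tobytes()).hexdigest()
        log.info("stage=%s source=%s hash=%s", stage, source, data_hash)

        stage = "summary"
        summary = summary_statistics(features)

        stage = "fits"
        fit_cfg = FitConfig(seed=config.seed)
        variants = {k: MODEL_VARIANTS[k] for k in config.variants}
        fits = fit_variants(features, variants, fit_cfg)
        ranking = compare_models(fits.values())

        stage = "tests"
        players = _player_indicator_table(features)
        rate_test = two_stage_bootstrap(players, null_rate=1.0 / 6.0,
                                        reps=config.reps, seed=config.seed + 1)
        lrt = mclachlan_lrt(features["arrivals"].to_numpy(int),
                            B=config.lrt_bootstrap, seed=config.seed + 2)
        ranks = features["informed_mean_start_rank"]
        if ranks.notna().all():
            k = int((ranks < 5.5).sum())
            rank_p = exact_binomial_test(k, len(ranks), 0.5, "greater")
            rank_test = {"k_below_middle": k, "n": len(ranks),
                         "proportion": k / len(ranks), "p_value": rank_p}
        else:
            rank_test = None

        stage = "figures"
        histograms = {
            name: histogram_series(features, fit, MODEL_VARIANTS[name])
            for name, fit in fits.items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "config": asdict(config),
        "source": source,
        "data_hash": data_hash,
        "n_groups": int(len(features)),
        "summary": summary.to_dict(orient="records"),
        "fits": {
            name: {
                "pi1": f.pi1, "pi2": f.pi2,
                "beta": dict(zip(f.beta_names, f.beta.tolist())),
                "z": dict(zip(f.beta_names,
                              [] if f.z_values is None else f.z_values.tolist())),
                "neg_loglik": f.neg_loglik, "p": f.n_params,
                "AIC": f.aic, "BIC": f.bic,
                "capped": f.capped.tolist() if f.capped is not None else None,
                "z_reliable": f.z_reliable,
            }
            for name, f in fits.items()
        },
        "ranking": ranking.to_dict(orient="records"),
        "tests": {
            "arrival_rate_bootstrap": {
                "observed": rate_test.observed, "p_value": rate_test.p_value,
                "reps": rate_test.reps, "seed": rate_test.seed,
                "null": rate_test.null,
            },
            "mixture_lrt": {
                "observed": lrt.observed, "p_value": lrt.p_value,
                "reps": lrt.reps, "seed": lrt.seed, "null": lrt.null,
            },
            "starting_rank_binomial": rank_test,
        },
        "wall_time_s": time.time() - t0,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        features.to_csv(out / "features.csv", index=False)
        table2_style(fits).to_csv(out / "model_table.csv", index=False)
        ranking.to_csv(out / "model_ranking.csv", index=False)
        for name, h in histograms.items():
            h.to_csv(out / f"histogram_{name}.csv", index=False)
    report["_fits"] = fits
    report["_features"] = features
    report["_histograms"] = histograms
    return report
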