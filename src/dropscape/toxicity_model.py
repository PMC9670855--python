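"""Random-forest prediction of mutation-induced cytotoxicity change.

A random-forest regressor maps the three delta features (delta p_DP,
delta p_AP, delta MBM) to the predicted change in condensate cytotoxicity
delta p_tox. Hyperparameters (ntree, the number of trees, and mtry, the
number of candidate features per split) are chosen by grid search using
out-of-bag (OOB) validation: each tree is fitted on a bootstrap draw of
about two-thirds of the data and validated on the remainder, and the grid
point maximising the Pearson correlation between OOB predictions and the
measured values wins. Ties break toward smaller ntree, then smaller mtry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .variant_features import FEATURE_COLUMNS

FORMAT_VERSION = 1

DEFAULT_NTREE_GRID = (100, 250, 500, 1000)
DEFAULT_MTRY_GRID = (1, 2, 3)


@dataclass
class ToxicityModel:
    """A trained forest with its grid-selected hyperparameters."""

    forest: RandomForestRegressor
    ntree: int
    mtry: int
    oob_r: float
    feature_names: list[str]
    seed: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mtry > len(self.feature_names):
            raise ValueError("mtry cannot exceed the number of features")
        if not -1.0 <= self.oob_r <= 1.0:
            raise ValueError(f"oob_r {self.oob_r} outside [-1, 1]")


def _feature_matrix(features: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    given = [c for c in features.columns if c in set(names)]
    if given != names:
        raise ValueError(f"feature columns {given} do not match expected order {names}")
    x = features[names].to_numpy(dtype=float)
    bad_rows = np.where(~np.isfinite(x).all(axis=1))[0]
    if bad_rows.size:
        raise ValueError(f"non-finite feature values in rows {bad_rows.tolist()[:10]}")
    return x


def evaluate(predictions, observations) -> float:
    """Pearson product-moment correlation between predictions and
    measured values."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if p.std() == 0 or o.std() == 0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(stats.pearsonr(p, o)[0])


def train(
    features: pd.DataFrame,
    targets,
    ntree_grid=DEFAULT_NTREE_GRID,
    mtry_grid=DEFAULT_MTRY_GRID,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ToxicityModel:
    """Grid-search a random forest by OOB Pearson correlation.

    Fits one forest per (ntree, mtry) pair with a fixed seed, scores each
    by the correlation between its out-of-bag predictions and the targets,
    and returns the winning model. The grid log (one row per pair) is kept
    in ``training_meta['grid']``.
    """
    names = feature_names or FEATURE_COLUMNS
    x = _feature_matrix(features, names)
    y = np.asarray(targets, dtype=float)
    if len(y) != len(x):
        raise ValueError("feature and target lengths differ")
    if len(y) < 30:
        raise ValueError(f"need at least 30 training rows, got {len(y)}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite target values")
    if y.std() == 0:
        raise ValueError("targets have zero variance")
    if x.std(axis=0).max() == 0:
        raise ValueError("all features are constant; nothing to split on")

    best = None
    grid_log = []
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            if mtry > len(names):
                raise ValueError(f"mtry {mtry} exceeds {len(names)} features")
            forest = RandomForestRegressor(
                n_estimators=ntree,
                max_features=mtry,
                oob_score=True,
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            forest.fit(x, y)
            oob_r = evaluate(forest.oob_prediction_, y)
            grid_log.append({"ntree": ntree, "mtry": mtry, "oob_r": oob_r})
            # strict > keeps the first (smallest ntree, then mtry) on ties
            if best is None or oob_r > best[0]:
                best = (oob_r, ntree, mtry, forest)

    oob_r, ntree, mtry, forest = best
    return ToxicityModel(
        forest=forest,
        ntree=ntree,
        mtry=mtry,
        oob_r=oob_r,
        feature_names=list(names),
        seed=seed,
        training_meta={
            "n_rows": len(y),
            "grid": grid_log,
            "ntree_grid": sorted(ntree_grid),
            "mtry_grid": sorted(mtry_grid),
        },
    )


def predict(model: ToxicityModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted delta p_tox for each row of a feature table.

    Columns must match the model's feature names in order.
    """
    x = _feature_matrix(features, model.feature_names)
    out = model.forest.predict(x)
    if not np.isfinite(out).all():
        raise ValueError("forest produced non-finite predictions")
    return out


def save_model(model: ToxicityModel, path) -> None:
    """Persist the model as a self-describing joblib bundle."""
    joblib.dump(
        {
            "format_version": FORMAT_VERSION,
            "forest": model.forest,
            "ntree": model.ntree,
            "mtry": model.mtry,
            "oob_r": model.oob_r,
            "feature_names": model.feature_names,
            "seed": model.seed,
            "training_meta": model.training_meta,
        },
        path,
    )


def load_model(path) -> ToxicityModel:
    """Load a persisted model; predictions are bit-identical to the
    original's."""
    try:
        bundle = joblib.load(path)
    except Exception as exc:  # corrupted / truncated file
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ValueError(f"{path} is not a dropscape model bundle")
    if bundle["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"model format version {bundle['format_version']} != {FORMAT_VERSION}"
        )
    return ToxicityModel(
        forest=bundle["forest"],
        ntree=bundle["ntree"],
        mtry=bundle["mtry"],
        oob_r=bundle["oob_r"],
        feature_names=bundle["feature_names"],
        seed=bundle["seed"],
        training_meta=bundle["training_meta"],
    )
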