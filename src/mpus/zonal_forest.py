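"""Zonally stratified random forest producing the multiparametric score.

The classifier forces its first decision to be the pixel's anatomical zone
(peripheral vs transition), realized as two independently grown forests —
one per stratum — because stiffness and contrast influx differ systematically
between zones.  Each stratum grows ``n_trees`` (default 1000) trees; before
growing a tree, six randomly chosen training patients are discarded entirely,
then 1/1000th of the remaining rows is bootstrapped with replacement.  Trees
split on cross-entropy (information gain), depth at most 50.

The multiparametric score of a pixel is the signed vote ratio
``(malignant votes - benign votes) / n_trees`` of its stratum, in [-1, 1];
positive scores indicate malignancy.  Score maps are spatially cleaned by a
median filter over a circular 15-pixel kernel (about 2.5 mm at the default
pixel spacing — roughly half the radius of a clinically significant lesion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from mpus.data_model import (
    LABEL_BENIGN,
    LABEL_MALIGNANT,
    ParamMap,
    RunConfig,
    ZONE_PZ,
    ZONE_TZ,
    FeatureTable,
    disk_offsets,
)
from mpus.map_radiomics import _kernel_reduce

ZONE_STRATA = {ZONE_PZ: "PZ", ZONE_TZ: "TZ"}


@dataclass
class TreeSpec:
    """Provenance of one grown tree: which patients were discarded and which
    rows (by patient) were bootstrapped."""

    discarded_patients: tuple[str, ...]
    bootstrap_row_index: np.ndarray          # indices into the stratum table
    bootstrap_patients: np.ndarray           # patient id per bootstrap row
    tree_seed: int


@dataclass
class StratumForest:
    zone: int
    trees: list[DecisionTreeClassifier]
    specs: list[TreeSpec]
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))


@dataclass
class ZonalForest:
    """Two-stratum forest with its feature manifest and training provenance."""

    strata: dict[int, StratumForest]
    feature_columns: list[str]
    seed: int
    config: RunConfig
    consulted: dict[int, int] = field(default_factory=dict)  # instrumentation

    def save(self, path) -> None:
        joblib.dump({"version": 1, "model": self}, path)

    @staticmethod
    def load(path) -> "ZonalForest":
        blob = joblib.load(path)
        if blob.get("version") != 1:
            raise ValueError("unrecognized model file version")
        return blob["model"]


def _stratum_seed(seed: int, zone: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), int(zone)])


def _draw_discard(rng: np.random.Generator, patients: np.ndarray,
                  groups: tuple[np.ndarray, np.ndarray], n_discard: int,
                  balanced: bool) -> np.ndarray:
    """Six random training patients to discard for one tree.

    When ``balanced`` and both classes have patients in the stratum, the
    draw is stratified so the surviving patients are split as evenly as
    possible between benign- and malignant-contributing patients (the side
    receiving the odd survivor is random).  This keeps the forest's prior
    for an unseen patient neutral: an unstratified draw lets the class whose
    patients happen to be more numerous pull every out-of-patient
    prediction toward itself.  ``groups`` must be in a label-invariant
    canonical order so that retraining with swapped labels consumes the
    random stream identically (score anti-symmetry).
    """
    ga, gb = groups
    if not balanced or len(ga) == 0 or len(gb) == 0:
        return rng.choice(patients, size=n_discard, replace=False)
    n_keep = len(patients) - n_discard
    keep_a = n_keep // 2
    if n_keep % 2 == 1:
        keep_a += int(rng.integers(0, 2))
    keep_a = int(np.clip(keep_a, max(1, n_keep - len(gb)), min(len(ga), n_keep - 1)))
    keep_b = n_keep - keep_a
    kept = np.concatenate([
        rng.choice(ga, size=keep_a, replace=False),
        rng.choice(gb, size=keep_b, replace=False),
    ])
    return np.setdiff1d(patients, kept)


def _train_stratum(df: pd.DataFrame, feature_columns: list[str], zone: int,
                   cfg: RunConfig, seed: int) -> StratumForest:
    sub = df[df["zone"] == zone].reset_index(drop=True)
    name = ZONE_STRATA[zone]
    y_all = (sub["label"].to_numpy() == LABEL_MALIGNANT).astype(int)
    if len(sub) == 0 or len(np.unique(y_all)) < 2:
        raise ValueError(f"stratum {name}: training data must contain both classes")
    X_all = sub[feature_columns].to_numpy(dtype=float)
    patients = np.sort(sub["patient_id"].unique())
    if len(patients) <= cfg.patients_discarded_per_tree:
        raise ValueError(
            f"stratum {name}: per-tree discarding of {cfg.patients_discarded_per_tree} "
            f"patients needs more than {cfg.patients_discarded_per_tree} patients, "
            f"got {len(patients)}"
        )
    rng = _stratum_seed(seed, zone)
    pid = sub["patient_id"].to_numpy()
    # partition patients by the majority class of their rows, then order the
    # two groups by a label-invariant key (their smallest member) so the
    # random stream is consumed identically under a label swap
    pat_class = {p: int(np.round(y_all[pid == p].mean())) for p in patients}
    g0 = np.array([p for p in patients if pat_class[p] == 0])
    g1 = np.array([p for p in patients if pat_class[p] == 1])
    if len(g0) and len(g1) and str(g1[0]) < str(g0[0]):
        groups = (g1, g0)
    else:
        groups = (g0, g1)
    trees: list[DecisionTreeClassifier] = []
    specs: list[TreeSpec] = []
    for _ in range(cfg.n_trees):
        discard = _draw_discard(rng, patients, groups,
                                cfg.patients_discarded_per_tree,
                                cfg.balanced_bootstrap)
        keep = np.nonzero(~np.isin(pid, discard))[0]
        n_boot = max(math.ceil(len(keep) * cfg.subsample_fraction), cfg.min_tree_rows)
        if cfg.balanced_bootstrap:
            # draw half the sample from each class, mirroring the balanced
            # benign/malignant pixel design of the training ROIs; guards
            # against majority drift when a held-out patient leaves their
            # class underrepresented in a stratum.  The two row groups are
            # visited in a label-invariant order (smallest row index first)
            # for the same anti-symmetry reason as the discard above.
            keep_pos = keep[y_all[keep] == 1]
            keep_neg = keep[y_all[keep] == 0]
            if len(keep_pos) == 0 or len(keep_neg) == 0:
                boot = keep[rng.integers(0, len(keep), size=n_boot)]
            else:
                row_groups = (keep_pos, keep_neg)
                if keep_neg[0] < keep_pos[0]:
                    row_groups = (keep_neg, keep_pos)
                half = max(n_boot // 2, 1)
                boot = np.concatenate([
                    row_groups[0][rng.integers(0, len(row_groups[0]), size=half)],
                    row_groups[1][rng.integers(0, len(row_groups[1]), size=half)],
                ])
        else:
            boot = keep[rng.integers(0, len(keep), size=n_boot)]
        tree_seed = int(rng.integers(0, 2 ** 31 - 1))
        tree = DecisionTreeClassifier(
            criterion=cfg.split_criterion,
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_leaf,
            max_features="sqrt",
            random_state=tree_seed,
        )
        # NaN features pass through: sklearn trees route missing values
        tree.fit(X_all[boot], y_all[boot])
        trees.append(tree)
        specs.append(TreeSpec(
            discarded_patients=tuple(sorted(discard.tolist())),
            bootstrap_row_index=boot.copy(),
            bootstrap_patients=pid[boot].copy(),
            tree_seed=tree_seed,
        ))
    return StratumForest(zone=zone, trees=trees, specs=specs)


def train(table: FeatureTable, config: RunConfig | None = None,
          seed: int = 0) -> ZonalForest:
    """Grow the two-stratum forest from labeled, non-calcified pixels.

    Requires more patients than are discarded per tree and both classes in
    every stratum present in the table.  Fully reproducible from ``seed``:
    each stratum derives an independent random stream from (seed, zone), so
    the model is bit-identical to two separately trained per-zone forests.
    """
    cfg = config or RunConfig()
    labeled = table.labeled(exclude_calcified=True)
    df = labeled.df
    if len(df) == 0:
        raise ValueError("no labeled, non-calcified training rows")
    n_pat = df["patient_id"].nunique()
    if n_pat <= cfg.patients_discarded_per_tree:
        raise ValueError(
            f"training requires at least {cfg.patients_discarded_per_tree + 1} "
            f"patients, got {n_pat}"
        )
    strata = {}
    for zone in sorted(set(df["zone"].unique()) & set(ZONE_STRATA)):
        strata[zone] = _train_stratum(df, table.feature_columns, int(zone), cfg, seed)
    if not strata:
        raise ValueError("training table contains no PZ or TZ rows")
    model = ZonalForest(strata=strata, feature_columns=list(table.feature_columns),
                        seed=seed, config=cfg)
    model._train_df = df  # retained for the zonal-equivalence structural check
    return model


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _tree_malignant_vote(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Per-sample malignant vote of one tree: 1 if the leaf's malignant
    fraction exceeds one half, 0 below, 0.5 on an exact tie.  The half-credit
    tie rule keeps the score exactly anti-symmetric under label swap."""
    proba = tree.predict_proba(X)
    classes = tree.classes_
    if len(classes) == 1:
        return np.full(len(X), float(classes[0]))
    p_mal = proba[:, int(np.nonzero(classes == 1)[0][0])]
    return np.where(p_mal > 0.5, 1.0, np.where(p_mal < 0.5, 0.0, 0.5))


def _stratum_votes(forest: StratumForest, X: np.ndarray) -> np.ndarray:
    votes = np.zeros(len(X))
    for tree in forest.trees:
        votes += _tree_malignant_vote(tree, X)
    return votes


def score(model: ZonalForest, table: FeatureTable) -> np.ndarray:
    """Multiparametric score per row: (malignant - benign votes) / n_trees,
    evaluated in the stratum given by the row's zone.  Rows whose zone has no
    stratum, or with no finite feature, are NaN."""
    if list(table.feature_columns) != list(model.feature_columns):
        raise ValueError("feature manifest of the table does not match the model")
    X = table.features()
    zones = table.df["zone"].to_numpy()
    out = np.full(len(X), np.nan)
    usable = np.isfinite(X).any(axis=1)
    for zone, forest in model.strata.items():
        m = (zones == zone) & usable
        if not m.any():
            continue
        n_trees = len(forest.trees)
        votes = _stratum_votes(forest, X[m])
        out[m] = (2.0 * votes - n_trees) / n_trees
        model.consulted[zone] = model.consulted.get(zone, 0) + int(m.sum())
    return out


def score_map(model: ZonalForest, table: FeatureTable,
              shape: tuple[int, int]) -> ParamMap:
    """Arrange per-row scores on the pixel grid as a score map in [-1, 1]."""
    s = score(model, table)
    values = np.full(shape, np.nan)
    rows = table.df["row"].to_numpy(int)
    cols = table.df["col"].to_numpy(int)
    values[rows, cols] = s
    return ParamMap(name="score", values=values, valid=np.isfinite(values), units="-")


def median_postfilter(smap: ParamMap, radius_px: int | None = None,
                      config: RunConfig | None = None) -> ParamMap:
    """Median of the score over a circular pixel kernel (15 px by default),
    intersected with valid pixels; invalid pixels stay invalid."""
    cfg = config or RunConfig()
    r = int(radius_px if radius_px is not None else cfg.median_filter_radius_px)
    offs = disk_offsets(r)
    med = _kernel_reduce(smap.values, offs, lambda s: np.nanmedian(s, axis=0))
    out = np.where(smap.valid, med, np.nan)
    return ParamMap(name=smap.name, values=out, valid=smap.valid.copy(),
                    units=smap.units)


# ---------------------------------------------------------------------------
# structural checks
# ---------------------------------------------------------------------------


def verify_patient_discard(model: ZonalForest) -> bool:
    """True iff no bootstrap row of any tree originates from a patient that
    was discarded for that tree."""
    for forest in model.strata.values():
        for spec in forest.specs:
            if np.isin(spec.bootstrap_patients, spec.discarded_patients).any():
                return False
    return True


def zonal_equivalence_check(model: ZonalForest, probe: FeatureTable,
                            config: RunConfig | None = None) -> dict:
    """Verify the forced zonal first split: the model's predictions must be
    identical to those of two forests trained independently on the PZ-only
    and TZ-only rows with the same per-stratum seeds.

    Returns a report dict with ``equal``, ``max_abs_diff`` and, on mismatch,
    ``first_diff`` (row index of the first differing probe sample).
    """
    cfg = config or model.config
    base = score(model, probe)
    # train one forest per zone on that zone's rows only, same seed
    per_zone = np.full(len(probe), np.nan)
    train_df = getattr(model, "_train_df", None)
    if train_df is None:
        raise ValueError("model lacks an attached training table; pass one via "
                         "model._train_df to run the equivalence check")
    for zone in model.strata:
        sub = FeatureTable(train_df[train_df["zone"] == zone].copy(),
                           model.feature_columns)
        solo = train(sub, cfg, model.seed)
        m = probe.df["zone"].to_numpy() == zone
        if m.any():
            per_zone[m] = score(solo, probe.subset(m))
    both = np.isfinite(base) & np.isfinite(per_zone)
    diffs = np.abs(base[both] - per_zone[both])
    nan_match = np.array_equal(np.isfinite(base), np.isfinite(per_zone))
    equal = bool(nan_match and (len(diffs) == 0 or diffs.max() == 0.0))
    report = {"equal": equal,
              "max_abs_diff": float(diffs.max()) if len(diffs) else 0.0}
    if not equal:
        where = np.nonzero((~np.isclose(base, per_zone, equal_nan=True)))[0]
        report["first_diff"] = int(where[0]) if len(where) else None
    return report
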