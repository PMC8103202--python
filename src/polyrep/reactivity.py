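"""ELISA reactivity calls, polyreactivity classification and strength summaries.

The classification rule follows standard polyreactivity panels: an antibody
positive against three or more of the six panel antigens (dsDNA, histone H1,
Ro52, LPS, insulin, ovalbumin) is *polyreactive*; positive against one or
two, *reactive*; against none, *non-reactive*.  Positivity itself is a
design decision (plate readers give no universal cutoff): the default policy
calls a well positive when its OD exceeds the blank mean + k standard
deviations (k = 3), with a fixed-cutoff policy available.  Thresholds are
recorded in the output provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("non-reactive", "reactive", "polyreactive")
POLYREACTIVE_MIN_ANTIGENS = 3


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


class ConfigurationError(ValueError):
    """Raised for invalid thresholding configurations."""


@dataclass(frozen=True)
class AntigenPanel:
    """Ordered antigen panel; order fixes heat-map column order."""

    antigens: tuple[str, ...] = ("dsDNA", "H1", "Ro52", "LPS", "Insulin", "OVA")

    def __post_init__(self):
        if len(set(self.antigens)) != len(self.antigens):
            raise ConfigurationError("antigen names must be unique")

    def __iter__(self):
        return iter(self.antigens)

    def __len__(self):
        return len(self.antigens)


DEFAULT_PANEL = AntigenPanel()


@dataclass
class ThresholdProvenance:
    policy: str
    k: float | None
    cutoff: float
    blank_mean: float | None = None
    blank_sd: float | None = None
    n_blanks: int | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def call_positivity(
    od_table: pd.DataFrame,
    blanks: pd.DataFrame | None = None,
    *,
    panel: AntigenPanel = DEFAULT_PANEL,
    policy: str = "adaptive",
    k: float = 3.0,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, ThresholdProvenance]:
    """Call per-antigen positivity from raw ODs.

    Parameters
    ----------
    od_table:
        One row per hybridoma with an ``id`` column and one OD column per
        panel antigen (extra metadata columns are ignored).
    blanks:
        Blank wells with an ``od`` column; required under the adaptive
        policy (at least 2 wells).
    policy:
        ``"adaptive"`` — positive iff OD > blank mean + k * blank SD;
        ``"fixed"`` — positive iff OD > ``cutoff``.

    Returns the boolean positivity table (indexed like ``od_table``, columns
    = panel antigens) and the threshold provenance.
    """
    missing = [ag for ag in panel if ag not in od_table.columns]
    if missing:
        raise SchemaError(f"OD table missing antigen columns: {missing}")

    if policy == "adaptive":
        if blanks is None or "od" not in getattr(blanks, "columns", ()) or len(blanks) < 2:
            raise ConfigurationError("adaptive policy requires >= 2 blank wells")
        mean = float(blanks["od"].mean())
        sd = float(blanks["od"].std(ddof=1))
        thr = mean + k * sd
        prov = ThresholdProvenance("adaptive", k, thr, mean, sd, len(blanks))
    elif policy == "fixed":
        if cutoff is None:
            raise ConfigurationError("fixed policy requires an explicit cutoff")
        thr = float(cutoff)
        prov = ThresholdProvenance("fixed", None, thr)
    else:
        raise ConfigurationError(f"unknown threshold policy {policy!r}")

    pos = pd.DataFrame({ag: od_table[ag] > thr for ag in panel}, index=od_table.index)
    if "id" in od_table.columns:
        pos.insert(0, "id", od_table["id"])
    return pos, prov


def classify(positivity: pd.DataFrame, *, panel: AntigenPanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Three-level reactivity category from a complete positivity table.

    Returns a frame with ``positive_count``, ``category`` and an
    ``anti_ro52`` flag (positivity against Ro52, implying >= 1 positive).
    """
    missing = [ag for ag in panel if ag not in positivity.columns]
    if missing:
        raise SchemaError(f"positivity table missing antigen columns: {missing}")
    counts = positivity[list(panel)].astype(bool).sum(axis=1)
    category = pd.cut(
        counts,
        bins=[-1, 0, POLYREACTIVE_MIN_ANTIGENS - 1, len(panel)],
        labels=CATEGORIES,
    ).astype(str)
    out = pd.DataFrame(index=positivity.index)
    if "id" in positivity.columns:
        out["id"] = positivity["id"]
    out["positive_count"] = counts
    out["category"] = category
    out["anti_ro52"] = positivity["Ro52"].astype(bool) if "Ro52" in positivity.columns else False
    return out


def classify_od_table(
    od_table: pd.DataFrame,
    blanks: pd.DataFrame | None = None,
    *,
    panel: AntigenPanel = DEFAULT_PANEL,
    policy: str = "adaptive",
    k: float = 3.0,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, ThresholdProvenance]:
    """Positivity + classification in one step, preserving metadata columns.

    Rows with a missing OD in any panel antigen are excluded from
    classification and returned with category ``"not-tested"`` so frequency
    denominators can count tested antibodies only.
    """
    tested = od_table.dropna(subset=list(panel))
    pos, prov = call_positivity(tested, blanks, panel=panel, policy=policy,
                                k=k, cutoff=cutoff)
    cls = classify(pos, panel=panel)
    meta_cols = [c for c in od_table.columns if c not in set(panel)]
    out = od_table[meta_cols].copy()
    out["positive_count"] = cls["positive_count"].reindex(out.index)
    out["category"] = cls["category"].reindex(out.index).fillna("not-tested")
    out["anti_ro52"] = (cls["anti_ro52"].reindex(out.index)
                        .astype("boolean").fillna(False).astype(bool))
    for ag in panel:
        out[f"positive_{ag}"] = (pos[ag].reindex(out.index)
                                 .astype("boolean").fillna(False).astype(bool))
    return out, prov


def build_heatmap_matrix(
    od_table: pd.DataFrame,
    *,
    panel: AntigenPanel = DEFAULT_PANEL,
    background: float = 0.0,
    sort_by: tuple[str, ...] = ("strain", "age_weeks", "isotype", "id"),
) -> pd.DataFrame:
    """Hybridoma x antigen OD matrix for heat-map rendering.

    Values are background-subtracted ODs clipped at 0; rows are ordered in
    blocks by strain, age and isotype, then id.  The index is the hybridoma
    id; the block columns are kept for downstream faceting.
    """
    if od_table.empty:
        raise ValueError("no profiles to build a heat map from")
    missing = [ag for ag in panel if ag not in od_table.columns]
    if missing:
        raise SchemaError(f"OD table missing antigen columns: {missing}")
    keys = [c for c in sort_by if c in od_table.columns]
    mat = od_table.sort_values(keys).reset_index(drop=True)
    block = mat[keys]
    values = (mat[list(panel)] - background).clip(lower=0.0)
    out = pd.concat([block, values], axis=1)
    if "id" in out.columns:
        out = out.set_index("id")
    return out


# ---------------------------------------------------------------------------
# dilution-series strength summaries

TITER_NEGATIVE = np.inf  # sentinel: never positive at any tested concentration


@dataclass
class StrengthSummary:
    hybridoma_id: str
    antigen: str
    endpoint_titer: float  # lowest concentration still positive (ug/mL)
    auc: float  # background-subtracted OD integrated over log10 concentration
    n_points: int = 0
    extras: dict = field(default_factory=dict)


def summarize_strength(
    curves: pd.DataFrame,
    *,
    threshold: float,
    background: float = 0.0,
) -> pd.DataFrame:
    """Endpoint titer and log-AUC per (hybridoma, antigen) dilution series.

    ``curves`` is tidy with columns id, antigen, concentration (ug/mL) and
    od.  Within each series concentrations must be strictly decreasing (the
    plate layout of a serial dilution); the endpoint titer is the smallest
    concentration whose OD exceeds ``threshold`` and the AUC integrates
    max(OD - background, 0) over log10 concentration by the trapezoid rule.
    All-negative series get an infinite titer sentinel.
    """
    for col in ("id", "antigen", "concentration", "od"):
        if col not in curves.columns:
            raise SchemaError(f"strength table missing column {col!r}")
    rows = []
    for (rid, ag), grp in curves.groupby(["id", "antigen"], sort=True):
        conc = grp["concentration"].to_numpy(float)
        od = grp["od"].to_numpy(float)
        if len(conc) < 3:
            raise ValueError(f"series ({rid}, {ag}): need >= 3 concentrations")
        if not (np.diff(conc) < 0).all():
            raise ValueError(f"series ({rid}, {ag}): concentrations must be strictly decreasing")
        positive = od > threshold
        titer = float(conc[positive].min()) if positive.any() else TITER_NEGATIVE
        x = np.log10(conc[::-1])
        y = np.clip(od[::-1] - background, 0.0, None)
        auc = float(np.trapezoid(y, x))
        rows.append({"id": rid, "antigen": ag, "endpoint_titer": titer,
                     "auc": auc, "n_points": len(conc)})
    return pd.DataFrame(rows)


def simulate_strength_curves(
    binding: dict[str, float],
    concentrations: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    hybridoma_id: str = "ab",
    od_max: float = 2.5,
    halfsat_conc: float = 1.0,
    noise_sigma: float = 0.0,
    bg_mean: float = 0.05,
) -> pd.DataFrame:
    """Emit a synthetic dilution series from latent binding strengths.

    The OD follows a saturating curve in (binding x concentration), so a
    higher-affinity antibody stays positive at lower concentrations —
    smaller endpoint titer, larger AUC — at an unchanged specificity set.
    """
    conc = np.asarray(concentrations, float)
    rows = []
    for ag, b in binding.items():
        x = b * conc
        signal = od_max * x / (x + halfsat_conc)
        if noise_sigma > 0 and rng is not None:
            signal = signal * np.exp(rng.normal(0, noise_sigma, size=len(conc)))
        rows.append(pd.DataFrame({
            "id": hybridoma_id, "antigen": ag,
            "concentration": conc, "od": signal + bg_mean,
        }))
    return pd.concat(rows, ignore_index=True)
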