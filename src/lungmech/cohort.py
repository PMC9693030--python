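"""Regional aggregation and cohort-level analyses.

Per-lobe summaries of the biomechanical maps, monotone trend detection of
group means across disease-stage groups, and Bland-Altman agreement between
measurement methods (limits of agreement = mean difference +/- 1.96 SD of
the differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import LOBE_LABELS, REGIONS, Volume
from .tensor_metrics import BiomechMaps, compute_biomech_maps, interior_mask

__all__ = [
    "RegionSummary",
    "BlandAltmanResult",
    "region_summary",
    "stage_trend",
    "bland_altman",
    "subject_summaries",
    "cohort_run",
    "ENTROPY_RANGES",
    "MEASURES",
]

#: fixed histogram ranges for entropy so values compare across subjects
ENTROPY_RANGES = {"J": (0.0, 4.0), "SRI": (0.0, 1.0), "ADI": (0.0, 4.0)}
ENTROPY_BINS = 64

#: the six cohort measures tracked across stages
MEASURES = ("J_mean", "J_std", "J_entropy", "J_rms", "ADI_mean", "SRI_entropy")


@dataclass
class RegionSummary:
    region: str
    measure: str
    mean: float
    std: float
    entropy: float
    rms: float
    n_valid: int


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def _histogram_entropy(values: np.ndarray, vrange: tuple[float, float]) -> float:
    """Shannon entropy (bits) of a fixed 64-bin histogram; 0 for one bin."""
    clipped = np.clip(values, *vrange)
    counts, _ = np.histogram(clipped, bins=ENTROPY_BINS, range=vrange)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _region_mask(lobes: Volume, region: str) -> np.ndarray:
    lab = np.asarray(lobes.data)
    if region == "LUNG":
        return lab > 0
    for code, name in LOBE_LABELS.items():
        if name == region:
            return lab == code
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def region_summary(
    map_vol: Volume,
    lobes: Volume,
    region: str,
    measure: str,
    valid: np.ndarray | None = None,
    exclude_boundary: bool = True,
) -> RegionSummary:
    """Mean/std/entropy/RMS of a map over the valid voxels of a region.

    NaN voxels (invalid map values, e.g. SRI where the deformation is
    isotropic) are excluded; the one-voxel boundary shell, where one-sided
    gradient stencils were used, is excluded by default.
    """
    mask = _region_mask(lobes, region)
    if exclude_boundary:
        mask &= interior_mask(map_vol.grid)
    vals = np.asarray(map_vol.data)[mask]
    if valid is not None:
        vals = np.asarray(map_vol.data)[mask & np.asarray(valid, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid voxels in region {region}")
    vrange = ENTROPY_RANGES.get(measure, (float(vals.min()), float(vals.max()) + 1e-9))
    return RegionSummary(
        region=region,
        measure=measure,
        mean=float(vals.mean()),
        std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        entropy=_histogram_entropy(vals, vrange),
        rms=float(np.sqrt(np.mean(vals**2))),
        n_valid=int(vals.size),
    )


def stage_trend(
    table: pd.DataFrame,
    measure: str,
    region: str = "LUNG",
    value_col: str = "value",
) -> dict:
    """Group means per stage, strict-monotonicity flag, and Spearman rho.

    ``table`` is long-format with at least columns ``stage``, ``measure``,
    ``region`` and ``value``; rows are filtered to the requested measure
    and region before grouping.
    """
    sub = table
    if "measure" in table.columns:
        sub = sub[sub["measure"] == measure]
    if "region" in table.columns and region is not None:
        sub = sub[sub["region"] == region]
    if sub.empty:
        raise ValueError(f"no rows for measure={measure} region={region}")
    groups = sub.groupby("stage")[value_col]
    if (groups.size() == 0).any() or groups.ngroups < 2:
        raise ValueError("need at least two nonempty stage groups")
    means = groups.mean().sort_index()
    d = np.diff(means.values)
    if np.all(d < 0):
        direction = "decreasing"
    elif np.all(d > 0):
        direction = "increasing"
    else:
        direction = "none"
    if sub[value_col].nunique() > 1:
        rho, pval = stats.spearmanr(sub["stage"], sub[value_col])
    else:
        rho, pval = 0.0, 1.0
    return {
        "measure": measure,
        "region": region,
        "stage_means": means.to_dict(),
        "direction": direction,
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
    }


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Paired-difference agreement: mean diff and mean +/- 1.96 SD limits.

    SD uses the n-1 denominator. Also returns the plot coordinates
    (pairwise means on the abscissa, differences on the ordinate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("methods must be paired: lengths differ")
    if x.size < 2:
        raise ValueError("need at least two paired observations")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        means=(x + y) / 2.0,
        diffs=d,
    )


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------


def subject_summaries(
    maps: BiomechMaps, lobes: Volume, regions: tuple[str, ...] = REGIONS
) -> list[dict]:
    """The six tracked measures for every region of one subject."""
    rows: list[dict] = []
    for region in regions:
        sj = region_summary(maps.J, lobes, region, "J")
        sa = region_summary(maps.ADI, lobes, region, "ADI")
        ss = region_summary(maps.SRI, lobes, region, "SRI")
        rows.extend(
            [
                {"region": region, "measure": "J_mean", "value": sj.mean},
                {"region": region, "measure": "J_std", "value": sj.std},
                {"region": region, "measure": "J_entropy", "value": sj.entropy},
                {"region": region, "measure": "J_rms", "value": sj.rms},
                {"region": region, "measure": "ADI_mean", "value": sa.mean},
                {"region": region, "measure": "SRI_entropy", "value": ss.entropy},
            ]
        )
    return rows


def _dvf_for_method(subject, method: str, reg_config=None):
    if method == "oracle":
        return subject.true_dvf
    if method == "sstvd":
        from .sstvd import RegistrationConfig, register_ct_pair

        if subject.ct_expiration is None:
            raise ValueError(f"subject {subject.subject_id} has no images")
        _, dvf, _ = register_ct_pair(
            subject.ct_expiration,
            subject.ct_inspiration,
            subject.lung_mask,
            reg_config or RegistrationConfig(),
        )
        return dvf
    raise ValueError(f"unknown method {method!r}")


def cohort_run(
    subjects,
    methods: tuple[str, ...] = ("oracle",),
    reg_config=None,
    external_dvfs: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compute maps and regional summaries for every subject x method.

    ``methods`` may include ``"oracle"`` (the generating ground-truth
    deformation), ``"sstvd"`` (the internal registration engine), or keys
    of ``external_dvfs`` mapping (subject_id, name) -> DisplacementField
    for fields produced by other registration tools.

    Returns a long-format table (subject_id, stage, method, region,
    measure, value) and a report with per-measure whole-lung stage trends,
    pairwise Bland-Altman of subject mean J, and any excluded subjects.
    """
    rows: list[dict] = []
    excluded: list[dict] = []
    for subject in subjects:
        for method in methods:
            try:
                if external_dvfs is not None and (subject.subject_id, method) in external_dvfs:
                    dvf = external_dvfs[(subject.subject_id, method)]
                else:
                    dvf = _dvf_for_method(subject, method, reg_config)
                maps = compute_biomech_maps(dvf)
                for r in subject_summaries(maps, subject.lobes):
                    rows.append(
                        {
                            "subject_id": subject.subject_id,
                            "stage": subject.stage,
                            "method": method,
                            **r,
                        }
                    )
            except Exception as exc:  # failed subject: record and continue
                excluded.append(
                    {
                        "subject_id": subject.subject_id,
                        "method": method,
                        "reason": str(exc),
                    }
                )
    table = pd.DataFrame(rows)
    report: dict = {"excluded": excluded, "trends": {}, "bland_altman": {}}
    if not table.empty:
        n_stages = table["stage"].nunique()
        for method in table["method"].unique():
            mtab = table[table["method"] == method]
            if n_stages >= 2:
                report["trends"][method] = {
                    m: stage_trend(mtab, m, "LUNG") for m in MEASURES
                }
        # pairwise agreement of whole-lung mean J between methods
        mj = table[(table.measure == "J_mean") & (table.region == "LUNG")]
        piv = mj.pivot_table(index="subject_id", columns="method", values="value")
        cols = list(piv.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                pair = piv[[a, b]].dropna()
                if len(pair) >= 2:
                    ba = bland_altman(pair[a].values, pair[b].values)
                    report["bland_altman"][f"{a}_vs_{b}"] = {
                        "mean_diff": ba.mean_diff,
                        "sd_diff": ba.sd_diff,
                        "loa_low": ba.loa_low,
                        "loa_high": ba.loa_high,
                        "n": int(len(pair)),
                    }
    return table, report
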