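"""Region-based volumetry and group statistics on label volumes.

Per-subject region volumes (voxel count x voxel volume) are expressed as a
percent of total labeled volume; group comparisons use pooled-variance
two-sample t-tests per region with Benjamini-Hochberg FDR control across the
region family, 95% confidence intervals of the mean difference, Cohen's d
(pooled SD), and the percent difference relative to the second group. Total
volume is compared across factor levels with one-way ANOVA.

Tables are plain pandas DataFrames: the cohort table has one row per subject
with metadata columns plus one ``pct_<region>`` column per region; the stats
table has one row per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def region_volumes(labels: np.ndarray, voxel_size: float) -> pd.DataFrame:
    """Per-region volume (mm^3) and percent of total labeled volume.

    Label 0 is background and excluded from the total.
    """
    if not np.issubdtype(np.asarray(labels).dtype, np.integer):
        raise ValueError("label volume must be integer typed")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    ids, counts = np.unique(labels, return_counts=True)
    keep = ids > 0
    ids, counts = ids[keep], counts[keep]
    if ids.size == 0:
        raise ValueError("no nonzero labels in volume")
    vol = counts * voxel_size**3
    total = vol.sum()
    return pd.DataFrame({"region": ids, "volume_mm3": vol,
                         "percent": 100.0 * vol / total})


def cohort_table(subject_labels: dict, voxel_size: float,
                 metadata: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-subject cohort table from label volumes.

    ``subject_labels`` maps subject ID to a label volume; ``metadata`` has a
    ``subject`` column plus group columns (genotype, sex, ...). Regions
    missing from a subject get 0%.
    """
    rows = []
    for subject, labels in subject_labels.items():
        rv = region_volumes(labels, voxel_size)
        row = {"subject": subject,
               "total_volume_mm3": float(rv["volume_mm3"].sum())}
        for _, r in rv.iterrows():
            row[f"pct_{int(r['region'])}"] = r["percent"]
        rows.append(row)
    table = pd.DataFrame(rows).fillna(0.0)
    return metadata.merge(table, on="subject", validate="one_to_one")


def _region_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c.startswith("pct_")]


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided pooled-variance two-sample t-test with CI and Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = ma - mb
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    d = diff / np.sqrt(sp2) if sp2 > 0 else 0.0
    return {"mean_a": ma, "sd_a": np.sqrt(va), "mean_b": mb,
            "sd_b": np.sqrt(vb), "t": float(t), "p": float(p),
            "ci_low": diff - tcrit * se, "ci_high": diff + tcrit * se,
            "cohen_d": float(d), "diff": diff,
            "pct_diff": 100.0 * diff / mb if mb != 0 else np.nan,
            "zero_variance": bool(sp2 == 0)}


def group_compare(table: pd.DataFrame, group_col: str, group_a: str,
                  group_b: str, alpha: float = 0.05,
                  region_cols=None) -> pd.DataFrame:
    """Per-region pooled t-tests (a vs b) with BH-FDR across all regions.

    Positive differences mean the region occupies a larger share of total
    volume in ``group_a``. Regions with zero pooled variance are flagged and
    excluded from the FDR family.
    """
    cols = list(region_cols) if region_cols is not None else _region_columns(table)
    if not cols:
        raise ValueError("no region columns (pct_*) in table")
    in_a = table[group_col] == group_a
    in_b = table[group_col] == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs n >= 2 subjects")
    rows = []
    for col in cols:
        res = pooled_ttest(table.loc[in_a, col].to_numpy(),
                           table.loc[in_b, col].to_numpy())
        res["region"] = col.removeprefix("pct_")
        rows.append(res)
    out = pd.DataFrame(rows)
    testable = ~out["zero_variance"]
    if testable.sum() and out.loc[testable, "p"].notna().all():
        reject, p_fdr, *_ = multipletests(out.loc[testable, "p"],
                                          alpha=alpha, method="fdr_bh")
        out.loc[testable, "p_fdr"] = p_fdr
        out.loc[testable, "significant"] = reject
    out["significant"] = out.get("significant", False)
    if out["zero_variance"].any():
        import warnings
        flagged = out.loc[out["zero_variance"], "region"].tolist()
        warnings.warn(f"regions with zero pooled variance excluded from the "
                      f"FDR family: {flagged}", stacklevel=2)
    order = ["region", "mean_a", "sd_a", "mean_b", "sd_b", "p", "p_fdr",
             "ci_low", "ci_high", "t", "cohen_d", "diff", "pct_diff",
             "significant", "zero_variance"]
    return out[order]


def anova_total_volume(table: pd.DataFrame, factor: str,
                       value_col: str = "total_volume_mm3") -> tuple[float, float]:
    """One-way ANOVA of total volume across the factor's levels."""
    groups = [g[value_col].to_numpy() for _, g in table.groupby(factor)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 factor levels")
    for g in groups:
        if g.size < 2:
            raise ValueError("every factor level needs n >= 2")
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        return 0.0, 1.0  # identical groups: no variance anywhere
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def synthesize_cohort(seed: int, n_regions: int = 330, n_a: int = 10,
                      n_b: int = 16, effect_regions: int = 0,
                      effect_size: float = 0.0,
                      group_col: str = "sex",
                      levels: tuple = ("F", "M")) -> pd.DataFrame:
    """Synthetic cohort of per-region percent volumes for statistics studies.

    Region means span the scale of real atlas tables (0.008-2.5% of total
    volume) with SDs around 15% of the mean; the first ``effect_regions``
    regions receive a mean shift of ``effect_size`` pooled SDs in group A.
    Values are drawn from normal distributions and clipped at 0.
    """
    rng = np.random.default_rng(seed)
    means = np.exp(rng.uniform(np.log(0.008), np.log(2.5), n_regions))
    sds = 0.15 * means
    rows = []
    for gi, (level, n) in enumerate(zip(levels, (n_a, n_b))):
        shift = np.zeros(n_regions)
        if gi == 0 and effect_regions:
            shift[:effect_regions] = effect_size * sds[:effect_regions]
        for s in range(n):
            vals = np.clip(rng.normal(means + shift, sds), 0, None)
            row = {"subject": f"{level}{s:02d}", group_col: level,
                   "total_volume_mm3": float(rng.normal(450.0, 30.0))}
            row.update({f"pct_{i + 1}": vals[i] for i in range(n_regions)})
            rows.append(row)
    return pd.DataFrame(rows)
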