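"""Nonparametric group comparisons for spontaneous and evoked metrics.

Electrode-level metrics (MFR, MBR, BD, PSTH areas, latencies) are rarely
normal, so comparisons use the rank-based Kruskal-Wallis test with tie
correction (latencies quantised to 4 ms bins are heavily tied).  A
Kolmogorov-Smirnov screen against a fitted normal is run first but is
advisory only: the pipeline always proceeds nonparametrically.  Raw
p-values are reported per comparison, without multiple-testing
correction; the number of comparisons is included so users can apply
their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ValidationError

__all__ = [
    "ComparisonResult",
    "normality_screen",
    "kruskal_wallis",
    "site_comparisons",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupDescriptor:
    label: str
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float


@dataclass(frozen=True)
class ComparisonResult:
    """Kruskal-Wallis outcome plus per-group descriptors."""

    groups: tuple[GroupDescriptor, ...]
    H: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _describe(label: str, x: np.ndarray) -> GroupDescriptor:
    return GroupDescriptor(
        label=label,
        n=x.size,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        q25=float(np.percentile(x, 25)),
        q75=float(np.percentile(x, 75)),
    )


def normality_screen(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """KS test of each group against a normal fitted to it (advisory).

    Returns a frame with columns label, n, ks_statistic, p_value,
    normal (bool; False for degenerate zero-variance groups).
    """
    rows = []
    for label, x in samples.items():
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValidationError(f"group {label!r} needs n >= 3")
        mu, sd = np.mean(x), np.std(x, ddof=1)
        if sd == 0:
            rows.append((label, x.size, np.nan, 0.0, False))
            continue
        stat, p = stats.kstest(x, "norm", args=(mu, sd))
        rows.append((label, x.size, float(stat), float(p), p >= ALPHA))
    return pd.DataFrame(
        rows, columns=["label", "n", "ks_statistic", "p_value", "normal"]
    )


def kruskal_wallis(groups: dict[str, np.ndarray]) -> ComparisonResult:
    """Kruskal-Wallis H test across two or more groups.

    H is computed on midranks with tie correction; the p-value comes
    from the chi-square approximation with (g - 1) degrees of freedom.
    Identical constant groups (zero H by construction) return p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = []
    for label, x in groups.items():
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        arrays.append(x)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations tied: no evidence of difference
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)
    descriptors = tuple(_describe(lab, np.asarray(x, float)) for lab, x in groups.items())
    return ComparisonResult(groups=descriptors, H=float(H), p_value=float(p))


def site_comparisons(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """All pairwise population/compartment comparisons of one metric.

    ``table`` is tidy with columns ``population`` (e.g. Cx/Hp),
    ``compartment``, ``stimulated_compartment``, and ``value_col``.
    Produces one row per comparison:

    - population contrasts (e.g. Cx vs Hp) within each
      (stimulated_compartment, compartment) cell, and
    - within-population across-compartment comparisons per stimulation
      site.

    Cells with an empty side are omitted (e.g. single-population input).
    """
    required = {"population", "compartment", "stimulated_compartment", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing columns {sorted(missing)}")
    rows = []
    pops = sorted(table["population"].unique())
    for stim_c in sorted(table["stimulated_compartment"].unique()):
        sub = table[table["stimulated_compartment"] == stim_c]
        for comp in sorted(sub["compartment"].unique()):
            cell = sub[sub["compartment"] == comp]
            for i, a in enumerate(pops):
                for b in pops[i + 1 :]:
                    va = cell.loc[cell["population"] == a, value_col].to_numpy()
                    vb = cell.loc[cell["population"] == b, value_col].to_numpy()
                    if va.size == 0 or vb.size == 0:
                        continue
                    res = kruskal_wallis({a: va, b: vb})
                    rows.append(
                        {
                            "comparison": "population",
                            "stimulated_compartment": stim_c,
                            "compartment": comp,
                            "group_a": a,
                            "group_b": b,
                            "n_a": va.size,
                            "n_b": vb.size,
                            "H": res.H,
                            "p": res.p_value,
                            "significant": res.significant,
                        }
                    )
        for pop in pops:
            psub = sub[sub["population"] == pop]
            comps = {
                c: g[value_col].to_numpy()
                for c, g in psub.groupby("compartment")
                if len(g) > 0
            }
            if len(comps) < 2:
                continue
            res = kruskal_wallis(comps)
            rows.append(
                {
                    "comparison": "compartments-within-population",
                    "stimulated_compartment": stim_c,
                    "compartment": "+".join(sorted(comps)),
                    "group_a": pop,
                    "group_b": "",
                    "n_a": sum(v.size for v in comps.values()),
                    "n_b": 0,
                    "H": res.H,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "stimulated_compartment",
            "compartment",
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "H",
            "p",
            "significant",
        ],
    )
    out.attrs["n_comparisons"] = len(out)
    return out
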