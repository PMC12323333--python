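"""Alpha diversity, composition summaries and differential-abundance screening.

Shannon diversity uses natural log by default (``-sum p_i ln p_i``), richness
is the observed count of non-zero taxa, composition tables report the top-N
groups at a chosen rank plus an "Other" bucket, and the genus screen is a
per-genus Kruskal-Wallis test across treatment groups with tie correction,
chi-square p-values and Benjamini-Hochberg q-values reported alongside
(STAMP-style practice flags on raw p; both decisions are returned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import CountTable, StudyDesign, ValidationError


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1); errors on zero-total samples."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total count: {zero}")
    return counts / totals


def shannon(proportions, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i (natural log unless `base` given)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative proportion passed to shannon()")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def observed_richness(counts) -> int:
    """Number of taxa with count (or proportion) > 0."""
    return int((np.asarray(counts) > 0).sum())


def diversity_report(table: CountTable, design: StudyDesign,
                     base: float | None = None) -> dict[str, pd.DataFrame]:
    """Per-sample Shannon/richness plus per-treatment summaries and
    pairwise Mann-Whitney p-values (BH-adjusted across pairs)."""
    props = relative_abundance(table)
    per_sample = pd.DataFrame({
        "shannon": props.apply(lambda c: shannon(c, base=base), axis=0),
        "richness": table.counts.apply(observed_richness, axis=0),
    })
    per_sample["treatment"] = design.table.loc[per_sample.index, "treatment"]
    groups = per_sample.groupby("treatment", sort=False)
    summary = groups[["shannon", "richness"]].agg(["mean", "std"])
    rows = []
    levels = list(design.treatments)
    for metric in ("shannon", "richness"):
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = per_sample.loc[per_sample["treatment"] == levels[i], metric]
                b = per_sample.loc[per_sample["treatment"] == levels[j], metric]
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append((metric, levels[i], levels[j], stat, p))
    pairwise = pd.DataFrame(rows, columns=["metric", "group_a", "group_b",
                                           "U", "p"])
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"per_sample": per_sample, "summary": summary, "pairwise": pairwise}


def top_n_composition(proportions: pd.DataFrame, lineage_names: pd.Series,
                      n: int = 20) -> pd.DataFrame:
    """Collapse proportions to named groups at a rank; keep the top `n` by
    overall mean abundance and pool the rest into "Other".

    `lineage_names` maps each taxon to its group label at the chosen rank
    (see :meth:`CountTable.rank_names`). Ties in mean abundance break
    lexicographically, so output is deterministic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    grouped = proportions.groupby(lineage_names.reindex(proportions.index)).sum()
    order = grouped.mean(axis=1).to_frame("mean")
    order["name"] = order.index
    ranked = order.sort_values(["mean", "name"],
                               ascending=[False, True]).index.tolist()
    keep = ranked[:n]
    out = grouped.loc[keep]
    other = grouped.drop(index=keep).sum(axis=0)
    if float(other.sum()) > 0 or len(ranked) > n:
        out.loc["Other"] = other
    return out


@dataclass
class DifferentialAbundanceResult:
    table: pd.DataFrame     # per genus: group means, H, df, p, q, flags
    alpha: float
    flag_on: str            # "p" (STAMP-style raw p) or "q"


def kruskal_genus_screen(proportions: pd.DataFrame, design: StudyDesign,
                         alpha: float = 0.05,
                         flag_on: str = "p") -> DifferentialAbundanceResult:
    """Kruskal-Wallis across treatments for every genus.

    Tie-corrected H with the chi-square approximation; all-identical
    abundances give H = 0, p = 1 by convention.  BH q-values are computed
    across all tested genera; significance is flagged on raw p by default
    with the q-decision reported alongside.
    """
    levels = list(design.treatments)
    if len(levels) < 2:
        raise ValidationError("need at least 2 treatment groups")
    sample_groups = [design.samples_for(t) for t in levels]
    rows = []
    for taxon in proportions.index:
        vals = [proportions.loc[taxon, s].to_numpy(dtype=float)
                for s in sample_groups]
        flat = np.concatenate(vals)
        if np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*vals)
        means = [float(v.mean()) for v in vals]
        rows.append([taxon, *means, float(h), len(levels) - 1, float(p),
                     levels[int(np.argmax(means))]])
    cols = (["taxon"] + [f"mean_{t}" for t in levels]
            + ["H", "df", "p", "direction"])
    df = pd.DataFrame(rows, columns=cols).set_index("taxon")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant_p"] = df["p"] < alpha
    df["significant_q"] = df["q"] < alpha
    df["significant"] = df["significant_p"] if flag_on == "p" else df["significant_q"]
    return DifferentialAbundanceResult(df, alpha, flag_on)


def kruskal_exact_p(groups: list[np.ndarray], n_perm: int | None = None,
                    rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for the Kruskal-Wallis H, as a cross-check.

    Exhaustive when the total arrangement count is small is impractical;
    a seeded Monte-Carlo permutation of group labels is used instead
    (`n_perm` defaults to 9999).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_perm = 9999 if n_perm is None else n_perm
    flat = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs, _ = stats.kruskal(*groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(flat)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        h, _ = stats.kruskal(*parts)
        if h >= h_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
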