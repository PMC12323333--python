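"""LDA-effect-size (LEfSe-style) screen for differential features.

Two stages, one-factor design (no subclass / pairwise Wilcoxon stage):

1. a Kruskal-Wallis test per feature across the treatment classes on
   intensities rescaled to a common per-sample total of 1e6 (the relative-
   intensity convention of the original method); features with p >= alpha
   are dropped;
2. for each surviving feature, over class-stratified bootstrap subsamples,
   a one-feature linear discriminant between the extreme classes (highest
   vs lowest class mean).  With a single feature the discriminant
   direction, normalized to unit length, projects the data onto itself, so
   the between-class difference of discriminant means equals the raw
   between-class mean difference; the per-bootstrap effect size is log10
   of the average of those two (identical) quantities, and the reported
   score is the bootstrap mean.

A feature passes when it survives stage 1 AND its mean score reaches the
LDA threshold (3.5 in the emulated screen; 2.0 is the common default of
the original tool).  Raising the threshold can only remove features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import StudyDesign, TraitTable, ValidationError


@dataclass
class LefseResult:
    table: pd.DataFrame          # per feature: kw_p, winning_class, score, passed
    alpha: float
    lda_threshold: float
    n_boot: int
    seed: int | None

    @property
    def passing(self) -> list[str]:
        return self.table.index[self.table["passed"]].tolist()


def tss_scale(table: pd.DataFrame, total: float = 1e6) -> pd.DataFrame:
    """Rescale each sample (row) to a common total intensity."""
    sums = table.sum(axis=1)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValidationError(f"samples with non-positive total intensity: {zero}")
    return table.div(sums, axis=0) * total


def lefse_screen(features: TraitTable, design: StudyDesign,
                 alpha: float = 0.05, lda_threshold: float = 3.5,
                 n_boot: int = 30, boot_fraction: float = 2 / 3,
                 seed: int | None = 0, scale_total: float = 1e6) -> LefseResult:
    """Run the two-stage screen over all features.

    Classes are the design's treatments; every class needs >= 3 samples.
    Deterministic given `seed`.
    """
    classes = list(design.treatments)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    groups = {c: design.samples_for(c) for c in classes}
    small = {c: len(s) for c, s in groups.items() if len(s) < 3}
    if small:
        raise ValidationError(f"classes with < 3 samples: {small}")

    x = tss_scale(features.table.loc[list(design.samples)], total=scale_total)
    idx = {c: np.array([x.index.get_loc(s) for s in groups[c]]) for c in classes}
    mat = x.to_numpy(dtype=float)
    names = list(x.columns)
    n_feat = mat.shape[1]

    kw_p = np.ones(n_feat)
    class_means = np.vstack([mat[idx[c]].mean(axis=0) for c in classes])
    for f in range(n_feat):
        vals = [mat[idx[c], f] for c in classes]
        flat = np.concatenate(vals)
        if np.all(flat == flat[0]):
            kw_p[f] = 1.0
        else:
            kw_p[f] = stats.kruskal(*vals).pvalue
    winning = np.array(classes)[np.argmax(class_means, axis=0)]
    survivors = np.flatnonzero(kw_p < alpha)

    scores = np.full(n_feat, np.nan)
    if len(survivors):
        rng = np.random.default_rng(seed)
        boot_scores = np.zeros((n_boot, len(survivors)))
        for b in range(n_boot):
            sub_idx = {c: rng.choice(idx[c],
                                     size=max(2, int(np.ceil(
                                         boot_fraction * len(idx[c])))),
                                     replace=False)
                       for c in classes}
            means = np.vstack([mat[sub_idx[c]][:, survivors].mean(axis=0)
                               for c in classes])
            diff = np.abs(means.max(axis=0) - means.min(axis=0))
            # unit-norm 1-D discriminant: the projected class-mean difference
            # equals the raw one, so their average is the difference itself
            boot_scores[b] = np.log10(np.maximum(diff, 1e-30))
        scores[survivors] = boot_scores.mean(axis=0)

    passed = (kw_p < alpha) & (np.nan_to_num(scores, nan=-np.inf) >= lda_threshold)
    df = pd.DataFrame({"kw_p": kw_p, "winning_class": winning,
                       "score": scores, "passed": passed}, index=names)
    df = df.sort_values("score", ascending=False, na_position="last")
    return LefseResult(df, alpha, lda_threshold, n_boot, seed)
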