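"""Synthetic drought-gradient study generator.

Emulates the structure of a pot-experiment microbiome study: six watering
treatments (a watered control plus five drought stages of increasing
severity), six biological replicates each, a genus-level fungal count
table, a six-indicator leaf-physiology panel, and an untargeted
root-metabolite intensity table.  Everything is planted with a recorded
ground truth (correlated taxon pairs, per-treatment hub taxa, abundance
trends, differential metabolites, taxon-linked metabolites) so that every
downstream stage — prevalence filtering, Spearman networks, core-taxon
calls, Kruskal-Wallis screens, Mantel tests, correlation heatmaps and the
LDA-effect-size screen — can be validated by recovery of known structure
rather than by eyeballing.

Counts are produced by a Gaussian copula with negative-binomial margins:
a latent multivariate normal per treatment carries the planted rank
correlation (Spearman is rank-based, so the copula correlation survives
the marginal transform almost unchanged), and the margins give integer,
overdispersed counts whose means follow per-taxon trend archetypes.
Per-sample sequencing depth is drawn log-uniformly and imposed exactly by
largest-remainder rescaling, which forces downstream code to work on
relative abundances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (CountTable, StudyDesign, TraitTable, format_lineage)

TREND_ARCHETYPES = ("flat", "increasing", "decreasing", "hump", "crash", "spike")

#: Physiology panel defaults: archetype, peak stage (hump/spike only),
#: relative amplitude, baseline in assay-kit units.  AsA rises and falls
#: with a ~21.5% peak at drought stage 3; GSSG declines; MDA and proline
#: rise monotonically to a late-drought maximum; SOD and soluble sugar are
#: unimodal with mid/late peaks.
PHYSIOLOGY_DEFAULTS: dict[str, dict] = {
    "AsA":  {"archetype": "hump", "peak": 3, "amplitude": 0.2153, "base": 50.0},
    "GSSG": {"archetype": "decreasing", "peak": None, "amplitude": 0.5, "base": 40.0},
    "MDA":  {"archetype": "increasing", "peak": None, "amplitude": 1.0, "base": 10.0},
    "Pro":  {"archetype": "increasing", "peak": None, "amplitude": 1.2, "base": 30.0},
    "SOD":  {"archetype": "hump", "peak": 3, "amplitude": 0.6, "base": 200.0},
    "SS":   {"archetype": "hump", "peak": 4, "amplitude": 0.5, "base": 20.0},
}

_PHYLA = ("Ascomycota", "Basidiomycota", "Mucoromycota", "Chytridiomycota")


class SynthError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults encode the emulated design: 6 treatments x 6 replicates,
    150 genera, 10 planted taxon pairs at latent rho 0.9, two hub taxa per
    treatment anchoring a shared latent "guild" factor of 32 partner taxa,
    and 200 metabolites of which 14 are differential.
    """

    n_treatments: int = 6
    n_replicates: int = 6
    n_taxa: int = 150
    planted_edges: list[tuple[int, int, float, int]] = None  # (i, j, rho, sign)
    hub_taxa: dict[int, list[int]] = None        # treatment index -> hub taxon ids
    hub_partners: int = 16                       # planted partners per hub (>= 8)
    hub_loading: float = 0.99                    # latent-factor loading of the hub
    partner_loading_range: tuple[float, float] = (0.70, 0.80)
    trend_assignments: dict[int, str] = None     # taxon id -> archetype
    trend_amplitude: float = 4.0                 # max fold change of taxon trends
    n_metabolites: int = 200
    n_diff_metabolites: int = 14
    diff_fold: float = 10.0                      # fold change of differential features
    n_linked_metabolites: int = 6                # metabolites tied to named taxa
    linked_rho: float = 0.9
    physiology: dict[str, dict] = None
    physiology_cv: float = 0.08
    metabolite_cv_log: float = 0.1               # sigma of within-class ln-intensity
    metabolite_log10_mu: float = 5.0             # cross-feature baseline location
    metabolite_log10_sigma: float = 0.25         # cross-feature baseline spread
    dispersion: float = 10.0                     # negative-binomial size parameter
    occupancy_range: tuple[float, float] = (0.2, 0.6)  # structural-zero rate of
    #                                            unstructured taxa (patchiness)
    library_size_range: tuple[int, int] = (10_000, 50_000)
    pd_repair_tol: float = 0.05                  # max tolerated planted-rho distortion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_edges is None:
            self.planted_edges = self.default_planted_edges()
        if self.hub_taxa is None:
            self.hub_taxa = self.default_hub_taxa()
        if self.trend_assignments is None:
            self.trend_assignments = self.default_trend_assignments()
        if self.physiology is None:
            self.physiology = {k: dict(v) for k, v in PHYSIOLOGY_DEFAULTS.items()}
        self.validate()

    # -- defaults -----------------------------------------------------------
    def default_planted_edges(self) -> list[tuple[int, int, float, int]]:
        """Ten vertex-disjoint pairs at latent rho 0.9 inside the hub guild.

        The pairs are drawn from the hub-partner pool: two guild members
        with factor loadings lam_i, lam_j can be lifted to correlation 0.9
        while staying positive definite (their residuals are correlated at
        (0.9 - lam_i lam_j)/sqrt((1-lam_i^2)(1-lam_j^2)) < 1), and pair
        members stay inside the main network component instead of forming
        isolated dyads whose classic closeness of 1.0 would distort the
        core-taxon quantile.
        """
        pool = self.hub_partner_ids(0) + self.hub_partner_ids(1)
        pool = [i for i in dict.fromkeys(pool) if i < self.n_taxa]
        n_pairs = min(10, len(pool) // 2)
        return [(pool[2 * k], pool[2 * k + 1], 0.9, 1) for k in range(n_pairs)]

    def default_hub_taxa(self) -> dict[int, list[int]]:
        hubs: dict[int, list[int]] = {}
        for t in range(self.n_treatments):
            a, b = 32 + 2 * t, 33 + 2 * t
            hubs[t] = [i for i in (a, b) if i < self.n_taxa]
        return hubs

    def hub_partner_ids(self, position: int) -> list[int]:
        """Partner taxa for the hub at `position` within a treatment.

        The partner pool (taxa from 50 up) is shared across treatments —
        each treatment has its own latent correlation matrix, so reusing
        partners keeps the number of structured (hence prevalent) taxa
        realistic.
        """
        start = 50 + self.hub_partners * position
        return [i % self.n_taxa for i in range(start, start + self.hub_partners)]

    def default_trend_assignments(self) -> dict[int, str]:
        """Taxa 0-9 carry the drought-response trends; the rest are flat.

        Emulates mid-drought-enriched genera (hump), a late-drought riser
        (increasing), a control-dominant decliner (crash/decreasing) and a
        stage-specific spike.
        """
        patterns = ["hump", "hump", "hump", "hump", "increasing",
                    "increasing", "decreasing", "crash", "spike", "spike"]
        return {i: patterns[i] for i in range(min(10, self.n_taxa))}

    def validate(self) -> None:
        if self.n_replicates < 3:
            raise SynthError("n_replicates must be >= 3 (rank correlation p-values "
                             "are not usable below that)")
        if self.n_diff_metabolites > self.n_metabolites:
            raise SynthError("n_diff_metabolites exceeds n_metabolites")
        seen = set()
        for (i, j, rho, sign) in self.planted_edges:
            if i == j:
                raise SynthError(f"planted self-pair ({i},{i})")
            if not (-1.0 < rho < 1.0):
                raise SynthError(f"planted rho out of (-1,1): {rho}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise SynthError(f"duplicate planted edge {key}")
            seen.add(key)
            if max(i, j) >= self.n_taxa:
                raise SynthError(f"planted edge {key} references unknown taxon")
        for t, hubs in self.hub_taxa.items():
            if not 0 <= t < self.n_treatments:
                raise SynthError(f"hub treatment index {t} out of range")
            for h in hubs:
                if h >= self.n_taxa:
                    raise SynthError(f"hub taxon {h} out of range")
        for taxon, arch in self.trend_assignments.items():
            if arch not in TREND_ARCHETYPES:
                raise SynthError(f"unknown trend archetype {arch!r} for taxon {taxon}")

    # -- derived labels -----------------------------------------------------
    @property
    def treatment_labels(self) -> list[str]:
        return ["control"] + [f"drought{k}" for k in range(1, self.n_treatments)]

    def taxon_ids(self) -> list[str]:
        width = len(str(self.n_taxa - 1))
        return [f"g{str(i).zfill(width)}" for i in range(self.n_taxa)]

    def metabolite_ids(self) -> list[str]:
        width = len(str(self.n_metabolites - 1))
        return [f"m{str(i).zfill(width)}" for i in range(self.n_metabolites)]


@dataclass
class SyntheticStudy:
    counts: CountTable
    design: StudyDesign
    physiology: TraitTable
    metabolites: TraitTable
    truth: dict


# ---------------------------------------------------------------------------
# trend archetypes
# ---------------------------------------------------------------------------

def trend_multiplier(archetype: str, t: int, n_treatments: int,
                     amplitude: float, peak: int | None = None) -> float:
    """Expected relative-abundance multiplier at treatment index ``t``.

    ``amplitude`` is the maximum fold change relative to the baseline;
    all archetypes return strictly positive values.
    """
    if n_treatments < 2:
        return 1.0
    x = t / (n_treatments - 1)
    pk = peak if peak is not None else (n_treatments - 1) // 2
    if archetype == "flat":
        return 1.0
    if archetype == "increasing":
        return 1.0 + (amplitude - 1.0) * x
    if archetype == "decreasing":
        return amplitude - (amplitude - 1.0) * x
    if archetype == "hump":
        span = max(pk, n_treatments - 1 - pk, 1)
        tri = 1.0 - abs(t - pk) / span
        return 1.0 + (amplitude - 1.0) * tri
    if archetype == "crash":
        # dominant in the control, collapsing with stress
        return amplitude * np.exp(-3.0 * x) + 1.0
    if archetype == "spike":
        return amplitude if t == pk else 1.0
    raise SynthError(f"unknown archetype {archetype!r}")


# ---------------------------------------------------------------------------
# latent correlation assembly
# ---------------------------------------------------------------------------

def assemble_latent_correlation(spec: SyntheticSpec, treatment: int,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, dict]:
    """Latent Gaussian correlation matrix for one treatment.

    Planted pairwise edges are written directly; each hub taxon gets a
    single-factor block (hub loading ``hub_loading``, partner loadings
    spread over ``partner_loading_range``) so the block is positive
    definite by construction and the hub is the strict correlation
    maximum.  Any residual indefiniteness is repaired by eigenvalue
    clipping; the repair aborts if it distorts a planted entry by more
    than ``pd_repair_tol``.
    """
    p = spec.n_taxa
    corr = np.eye(p)
    planted: list[tuple[int, int, float]] = []
    for (i, j, rho, sign) in spec.planted_edges:
        # chain edges share taxa: fill AR(1)-style products for consistency
        corr[i, j] = corr[j, i] = rho * sign
        planted.append((i, j, rho * sign))
    # AR(1) completion along the default chain keeps the block PD: any two
    # chain taxa get the product of the rhos on the path between them.
    _complete_chains(corr, spec.planted_edges)

    # hubs anchor one shared "guild" factor per treatment: every hub loads
    # high, partners lower, so hubs correlate strongly with the whole
    # partner pool (high degree AND short paths to a third of the
    # prevalent community) while partner-partner correlations are the
    # weaker loading products
    hub_blocks = []
    hubs = list(spec.hub_taxa.get(treatment, []))
    if hubs:
        partners: list[int] = []
        for h_pos in range(len(hubs)):
            partners.extend(spec.hub_partner_ids(h_pos))
        partners = [q for q in dict.fromkeys(partners) if q not in hubs]
        lam = np.empty(len(hubs) + len(partners))
        lam[:len(hubs)] = spec.hub_loading
        lam[len(hubs):] = np.linspace(*spec.partner_loading_range, len(partners))
        planted_keys = {(min(i, j), max(i, j)) for (i, j, *_r) in spec.planted_edges}
        block = hubs + partners
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                i, j = block[a], block[b]
                if (min(i, j), max(i, j)) in planted_keys:
                    continue  # planted pair correlations take precedence
                corr[i, j] = corr[j, i] = lam[a] * lam[b]
        for hub in hubs:
            hub_blocks.append({"hub": hub, "partners": partners,
                               "loadings": lam.tolist()})

    repaired, distortion = _nearest_pd(corr)
    bad = [(i, j) for (i, j, rho) in planted
           if abs(repaired[i, j] - rho) > spec.pd_repair_tol]
    if bad:
        raise SynthError(
            "planted correlation matrix could not be repaired to positive "
            f"definite without distorting planted edges {bad} beyond "
            f"tolerance {spec.pd_repair_tol}")
    info = {"hub_blocks": hub_blocks, "max_pd_distortion": float(distortion)}
    return repaired, info


def _complete_chains(corr: np.ndarray, edges: Sequence[tuple]) -> None:
    """Fill transitive entries of simple chains with products of edge rhos."""
    adj: dict[int, list[tuple[int, float]]] = {}
    for (i, j, rho, sign) in edges:
        adj.setdefault(i, []).append((j, rho * sign))
        adj.setdefault(j, []).append((i, rho * sign))
    if any(len(v) > 2 for v in adj.values()):
        return  # not a disjoint union of chains; leave to eigenvalue repair
    seen: set[int] = set()
    for start in adj:
        if start in seen or len(adj[start]) != 1:
            continue
        path = [start]
        rhos: list[float] = []
        prev, cur = None, start
        while True:
            nxt = [(n, r) for n, r in adj[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0][0]
            rhos.append(nxt[0][1])
            path.append(cur)
        seen.update(path)
        for a in range(len(path)):
            acc = 1.0
            for b in range(a + 1, len(path)):
                acc *= rhos[b - 1]
                corr[path[a], path[b]] = corr[path[b], path[a]] = acc


def _nearest_pd(corr: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped positive-definite repair, unit diagonal restored."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= floor:
        return corr, 0.0
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, float(np.abs(fixed - corr).max())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _make_design(spec: SyntheticSpec) -> StudyDesign:
    rows = []
    for t, label in enumerate(spec.treatment_labels):
        for r in range(spec.n_replicates):
            rows.append((f"{label}_r{r + 1}", label, r + 1))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "replicate"]
                      ).set_index("sample_id")
    return StudyDesign(df, tuple(spec.treatment_labels))


def _baseline_abundance(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Cross-taxon baseline relative abundances (heavy-tailed log-normal).

    Genus-level amplicon tables are sparse: a few dominant genera and a
    long tail of rare ones that fail an 80% prevalence filter, which is
    what keeps real co-occurrence networks at a few dozen nodes.  Taxa
    that carry planted structure (trend taxa, the correlation chain, hubs
    and their partners) are remapped into the abundant tier so the planted
    structure is observable after filtering.
    """
    base = rng.lognormal(mean=0.0, sigma=2.0, size=spec.n_taxa)
    idx = np.fromiter(sorted(_structured_taxa(spec)), dtype=int)
    base[idx] = np.quantile(base, rng.uniform(0.70, 0.85, size=len(idx)))
    return base / base.sum()


def _structured_taxa(spec: SyntheticSpec) -> set[int]:
    structured = set(spec.trend_assignments)
    for (i, j, *_rest) in spec.planted_edges:
        structured.update((i, j))
    if spec.hub_taxa:
        for hubs in spec.hub_taxa.values():
            structured.update(hubs)
        for pos in range(max(len(h) for h in spec.hub_taxa.values())):
            structured.update(spec.hub_partner_ids(pos))
    return structured


def _taxonomy(spec: SyntheticSpec, rng: np.random.Generator) -> pd.Series:
    ids = spec.taxon_ids()
    lineages = {}
    for i, tid in enumerate(ids):
        phylum = _PHYLA[rng.integers(len(_PHYLA))]
        klass = f"{phylum[:4]}_class{rng.integers(3) + 1}"
        order = f"{klass}_ord{rng.integers(3) + 1}"
        family = f"{order}_fam{rng.integers(3) + 1}"
        genus = f"Genus_{tid}"
        lineages[tid] = format_lineage({"phylum": phylum, "class": klass,
                                        "order": order, "family": family,
                                        "genus": genus})
    return pd.Series(lineages)


def generate_counts(spec: SyntheticSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[CountTable, StudyDesign, dict]:
    """Copula + negative-binomial counts for the full design.

    Returns the count table, the matching design, and the truth record
    (planted edges, hub blocks, realized latent correlations per
    treatment, trend assignments, per-sample library sizes).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    design = _make_design(spec)
    base = _baseline_abundance(spec, rng)
    lineages = _taxonomy(spec, rng)
    ids = spec.taxon_ids()

    # patchy occupancy: unstructured taxa can be structurally absent from a
    # pot, which is what keeps the 80% prevalence filter selective.
    # Occupancy rises with abundance (dominant genera are everywhere; only
    # rare ones are patchy) — abundance-independent dropout of a dominant
    # taxon would swing sample totals and induce spurious compositional
    # correlations among all other taxa.
    occupancy = np.ones(spec.n_taxa)
    unstructured = np.array(sorted(set(range(spec.n_taxa))
                                   - _structured_taxa(spec)), dtype=int)
    if len(unstructured):
        u = rng.uniform(*spec.occupancy_range, size=len(unstructured))
        abundance_rank = stats.rankdata(base[unstructured]) / len(unstructured)
        occupancy[unstructured] = np.where(abundance_rank > 0.8, 1.0, u)

    lo, hi = spec.library_size_range
    n_samples = spec.n_treatments * spec.n_replicates
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples)
                       ).round().astype(int)
    lib_sizes = np.clip(lib_sizes, lo, hi)

    ref_depth = int(np.sqrt(lo * hi))
    cols = {}
    truth_corr = {}
    hub_info = {}
    max_distortion = 0.0
    s_idx = 0
    for t, label in enumerate(spec.treatment_labels):
        corr, info = assemble_latent_correlation(spec, t, rng)
        truth_corr[label] = corr
        hub_info[label] = info["hub_blocks"]
        max_distortion = max(max_distortion, info["max_pd_distortion"])
        mult = np.array([trend_multiplier(spec.trend_assignments.get(i, "flat"),
                                          t, spec.n_treatments,
                                          spec.trend_amplitude)
                         for i in range(spec.n_taxa)])
        rel = base * mult
        rel = rel / rel.sum()
        mu = np.maximum(rel * ref_depth, 1e-9)
        chol = np.linalg.cholesky(corr)
        size = spec.dispersion
        for r in range(spec.n_replicates):
            z = chol @ rng.standard_normal(spec.n_taxa)
            u = stats.norm.cdf(z)
            u = np.clip(u, 1e-12, 1 - 1e-12)
            x = stats.nbinom.ppf(u, size, size / (size + mu)).astype(np.int64)
            x = x * (rng.random(spec.n_taxa) < occupancy)
            cols[f"{label}_r{r + 1}"] = _rescale_to_depth(x, lib_sizes[s_idx])
            s_idx += 1

    counts = pd.DataFrame(cols, index=ids)
    table = CountTable(counts, lineages)
    truth = {
        "planted_edges": [[ids[i], ids[j], rho, sign]
                          for (i, j, rho, sign) in spec.planted_edges],
        "hub_taxa": {label: [{"hub": ids[b["hub"]],
                              "partners": [ids[q] for q in b["partners"]],
                              "loadings": b["loadings"]}
                             for b in hub_info[label]]
                     for label in spec.treatment_labels},
        "trend_assignments": {ids[i]: a for i, a in spec.trend_assignments.items()},
        "latent_correlation": {label: truth_corr[label].tolist()
                               for label in spec.treatment_labels},
        "max_pd_distortion": max_distortion,
        "library_sizes": {s: int(v) for s, v in
                          zip(design.samples, lib_sizes)},
    }
    return table, design, truth


def _rescale_to_depth(x: np.ndarray, depth: int) -> np.ndarray:
    """Scale non-negative counts to sum exactly `depth` (largest remainder)."""
    total = x.sum()
    if total == 0:
        out = np.zeros_like(x)
        out[0] = depth
        return out
    target = x * (depth / total)
    out = np.floor(target).astype(np.int64)
    short = depth - out.sum()
    if short > 0:
        frac = target - out
        out[np.argsort(-frac, kind="stable")[:short]] += 1
    return out


def generate_physiology(spec: SyntheticSpec, design: StudyDesign,
                        rng: np.random.Generator | None = None) -> TraitTable:
    """Leaf-physiology panel following the per-indicator trend archetypes."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    t_index = design.treatment_index()
    data = {}
    for name, cfg in spec.physiology.items():
        arch = cfg["archetype"]
        if arch not in TREND_ARCHETYPES:
            raise SynthError(f"unknown physiology archetype {arch!r} for {name}")
        means = np.array([cfg["base"] * trend_multiplier(
            arch, int(t), spec.n_treatments, 1.0 + cfg["amplitude"],
            cfg.get("peak")) for t in t_index])
        noise = rng.normal(0.0, spec.physiology_cv, size=len(means))
        data[name] = means * (1.0 + noise)
    return TraitTable(pd.DataFrame(data, index=design.samples))


def generate_metabolites(spec: SyntheticSpec, design: StudyDesign,
                         counts: CountTable,
                         rng: np.random.Generator | None = None
                         ) -> tuple[TraitTable, dict]:
    """Log-normal metabolite intensities with planted differential features.

    The first ``n_diff_metabolites`` planted features follow strong
    treatment trends (fold change ``diff_fold``); ``n_linked_metabolites``
    further features are noisy monotone functions of named taxa's relative
    abundances, planting recoverable taxon x metabolite correlations.
    Differential and linked feature identities are drawn from the RNG and
    recorded in the returned truth dict.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    if spec.n_diff_metabolites > spec.n_metabolites:
        raise SynthError("n_diff_metabolites exceeds n_metabolites")
    ids = spec.metabolite_ids()
    n = len(design.samples)
    t_index = design.treatment_index().to_numpy()

    log10_base = rng.normal(spec.metabolite_log10_mu, spec.metabolite_log10_sigma,
                            size=spec.n_metabolites)
    base = 10.0 ** log10_base

    perm = rng.permutation(spec.n_metabolites)
    diff_ids = sorted(perm[:spec.n_diff_metabolites].tolist())
    pool = perm[spec.n_diff_metabolites:]
    n_linked = min(spec.n_linked_metabolites, len(pool))
    linked_ids = sorted(pool[:n_linked].tolist())

    # balanced trend directions: planted differential features rise and fall
    # in equal measure so the per-sample total intensity stays stable and
    # total-sum normalization does not smear the planted signal onto
    # non-differential features; directions alternate down the baseline
    # ranking so the up- and down-moving intensity masses match closely
    diff_archetypes = ("increasing", "decreasing", "hump", "crash")
    by_base = sorted(diff_ids, key=lambda f: -base[f])
    arch_of = {f: diff_archetypes[r % len(diff_archetypes)]
               for r, f in enumerate(by_base)}
    diff_truth = []
    intensity = np.empty((n, spec.n_metabolites))
    for f in range(spec.n_metabolites):
        mult = np.ones(n)
        if f in diff_ids:
            arch = arch_of[f]
            mult = np.array([trend_multiplier(arch, int(t), spec.n_treatments,
                                              spec.diff_fold) for t in t_index])
        noise = rng.lognormal(0.0, spec.metabolite_cv_log, size=n)
        intensity[:, f] = base[f] * mult * noise
        if f in diff_ids:
            means = [intensity[t_index == t, f].mean()
                     for t in range(spec.n_treatments)]
            diff_truth.append({"metabolite": ids[f],
                               "archetype": arch,
                               "winning_class": spec.treatment_labels[
                                   int(np.argmax(means))]})

    # taxon-linked features: log-intensity = rho * standardized taxon signal
    # + sqrt(1-rho^2) * gaussian noise, a Gaussian-copula-style plant whose
    # Spearman correlation with the taxon is ~linked_rho
    rel = counts.counts.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=0, keepdims=True)
    link_targets = []
    chain_taxa = sorted({i for e in spec.planted_edges for i in e[:2]})
    candidates = chain_taxa if chain_taxa else list(range(spec.n_taxa))
    sample_order = list(design.samples)
    col_pos = [list(counts.samples).index(s) for s in sample_order]
    for k, f in enumerate(linked_ids):
        taxon = candidates[k % len(candidates)]
        sig = rel[taxon, col_pos]
        ranks = stats.rankdata(sig)
        z = stats.norm.ppf(ranks / (len(ranks) + 1.0))
        eps = rng.standard_normal(n)
        rho = spec.linked_rho
        logi = (np.log(base[f]) +
                0.5 * (rho * z + np.sqrt(1 - rho ** 2) * eps))
        intensity[:, f] = np.exp(logi)
        link_targets.append({"metabolite": ids[f],
                             "taxon": counts.taxa[taxon],
                             "rho": rho})

    table = TraitTable(pd.DataFrame(intensity, index=design.samples, columns=ids))
    truth = {"differential_metabolites": diff_truth,
             "linked_metabolites": link_targets}
    return table, truth


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Full study: counts, design, physiology, metabolites and one truth record."""
    root = np.random.SeedSequence(spec.seed)
    r_counts, r_phys, r_met = (np.random.default_rng(s) for s in root.spawn(3))
    counts, design, truth_c = generate_counts(spec, r_counts)
    physiology = generate_physiology(spec, design, r_phys)
    metabolites, truth_m = generate_metabolites(spec, design, counts, r_met)
    truth = {**truth_c, **truth_m,
             "spec": {k: v for k, v in dataclasses.asdict(spec).items()
                      if k != "physiology"}}
    _check_truth(truth, counts, metabolites)
    return SyntheticStudy(counts, design, physiology, metabolites, truth)


def _check_truth(truth: dict, counts: CountTable, mets: TraitTable) -> None:
    taxa = set(counts.taxa)
    feats = set(mets.traits)
    for (a, b, *_r) in truth["planted_edges"]:
        assert a in taxa and b in taxa
    for rec in truth["differential_metabolites"]:
        assert rec["metabolite"] in feats
    for rec in truth["linked_metabolites"]:
        assert rec["metabolite"] in feats and rec["taxon"] in taxa


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Write counts/design/physiology/metabolites as TSV and truth as JSON."""
    from . import tables_io as io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "physiology": outdir / "physiology.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_count_table(study.counts, paths["counts"])
    io.write_design(study.design, paths["design"])
    io.write_traits(study.physiology, paths["physiology"])
    io.write_traits(study.metabolites, paths["metabolites"])
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    paths["truth"].write_text(json.dumps(study.truth, indent=1, default=_default,
                                         sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
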