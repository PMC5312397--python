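"""Barcode clustering, heatmap export, and panel-level statistics.

Hierarchical clustering of categorical barcodes (the registry heatmap view),
the random-match probability of the panel, its biobank birthday-bound
collision risk, and simulation-based detection-limit power curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .authenticate import (
    DEFAULT_DETECTION,
    DetectionThresholds,
    Disposition,
    compare_profiles,
    detect_contamination,
)
from .panel import Category, SNPAssay, SNPProfile, assign_references, default_panel
from .signal import CallThresholds, DEFAULT_THRESHOLDS
from .simulate import (
    MixtureSpec,
    SimulationConfig,
    simulate_mixture,
    simulate_profiles,
    traces_for_profile,
)


def genotype_distance(
    a: SNPProfile, b: SNPProfile, assays: tuple[SNPAssay, ...] | None = None
) -> float:
    """Categorical barcode distance: (strong + 0.5*weak) / informative.

    0 for identical profiles, 1 for opposite homozygotes everywhere; defined
    as 1 when no locus is informative.
    """
    c = compare_profiles(a, b, assays)
    if c.n_informative == 0:
        return 1.0
    return (c.n_strong_mismatch + 0.5 * c.n_weak_mismatch) / c.n_informative


@dataclass(slots=True)
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be >= 0")


def distance_matrix(
    profiles: list[SNPProfile], assays: tuple[SNPAssay, ...] | None = None
) -> DistanceMatrix:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = genotype_distance(profiles[i], profiles[j], assays)
    return DistanceMatrix(ids=[p.sample_id for p in profiles], d=d)


@dataclass(slots=True)
class Dendrogram:
    """Agglomeration result: scipy-style merge list plus the leaf order.

    ``merges[k] = (i, j, height, size)`` merges clusters i and j (ids 0..n-1
    are leaves; merge k creates cluster n+k), exactly the scipy linkage
    encoding.
    """

    ids: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]

    def linkage(self) -> np.ndarray:
        """The merges as a scipy-compatible (n-1, 4) linkage array."""
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    def cut(self, height: float) -> list[set[str]]:
        """Flat clusters obtained by cutting all merges above *height*."""
        n = len(self.ids)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (i, j, h, _s) in enumerate(self.merges):
            if h <= height:
                members[n + k] = members.pop(i) | members.pop(j)
        return sorted(
            ({self.ids[i] for i in grp} for grp in members.values()),
            key=lambda s: sorted(s),
        )


def hierarchical_cluster(matrix: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with deterministic lowest-index tie-breaking.

    ``average`` (UPGMA) or ``complete`` linkage.  At every step the pair with
    minimal inter-cluster distance merges; exact ties go to the lexically
    smallest (i, j) cluster-id pair, so the result is reproducible and
    identical profiles merge first at height 0.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(matrix.ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return Dendrogram(ids=list(matrix.ids), merges=[], leaf_order=[0])
    # active cluster id -> (leaf set, size); leaves are 0..n-1, merges n, n+1, ...
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(matrix.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_id
        next_id += 1
        members_i, members_j = active.pop(i), active.pop(j)
        merged = members_i | members_j
        for k in list(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dik, djk = dist.pop(a), dist.pop(b)
            if linkage == "average":
                dk = (len(members_i) * dik + len(members_j) * djk) / len(merged)
            else:
                dk = max(dik, djk)
            dist[(k, new)] = dk
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        active[new] = merged
        children[new] = (i, j)
        merges.append((i, j, h, len(merged)))

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return _leaves(left) + _leaves(right)

    return Dendrogram(ids=list(matrix.ids), merges=merges, leaf_order=_leaves(next_id - 1))


# --- heatmap ----------------------------------------------------------------

#: Category -> heatmap color (homozygous allele 1 red, allele 2 blue,
#: heterozygous green, no-amplification/undetermined white).
HEATMAP_COLORS = {
    Category.HOM1: "#d62728",
    Category.HOM2: "#1f77b4",
    Category.HET: "#2ca02c",
    Category.NOAMP: "#ffffff",
    Category.UNDET: "#ffffff",
}

_CODE = {Category.HOM1: 0, Category.HOM2: 1, Category.HET: 2, Category.NOAMP: 3, Category.UNDET: 3}


def heatmap_export(
    profiles: list[SNPProfile],
    leaf_order: list[int],
    path,
    tsv_path=None,
) -> None:
    """Render the barcode matrix in leaf order and write the ordered call TSV.

    The image format follows the *path* extension (png/pdf/svg); *tsv_path*
    defaults to *path* with a ``.tsv`` suffix.  The TSV (samples x assays,
    category names) round-trips via :func:`read_call_matrix_tsv`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    if not profiles:
        raise ValueError("no profiles to render")
    ordered = [profiles[i] for i in leaf_order]
    assay_ids = list(ordered[0].calls)
    codes = np.array([[_CODE[p.category(a)] for a in assay_ids] for p in ordered])

    cmap = ListedColormap(["#d62728", "#1f77b4", "#2ca02c", "#ffffff"])
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.22 * len(assay_ids)), max(3.0, 0.18 * len(ordered)))
    )
    ax.imshow(codes, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(len(assay_ids)))
    ax.set_xticklabels(assay_ids, rotation=90, fontsize=5)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([p.sample_id for p in ordered], fontsize=5)
    ax.legend(
        handles=[
            Patch(color="#d62728", label="Homozygous allele 1"),
            Patch(color="#1f77b4", label="Homozygous allele 2"),
            Patch(color="#2ca02c", label="Heterozygous"),
            Patch(color="#ffffff", ec="0.5", label="No amplification / undetermined"),
        ],
        loc="upper left",
        bbox_to_anchor=(1.01, 1.0),
        fontsize=6,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    if tsv_path is None:
        tsv_path = str(path).rsplit(".", 1)[0] + ".tsv"
    df = pd.DataFrame(
        [[p.category(a).value for a in assay_ids] for p in ordered],
        index=[p.sample_id for p in ordered],
        columns=assay_ids,
    )
    df.to_csv(tsv_path, sep="\t", index_label="sample_id")


def read_call_matrix_tsv(path) -> pd.DataFrame:
    """Read back a heatmap TSV (index sample_id, category-valued cells)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    for col in df.columns:
        df[col] = df[col].map(Category)
    return df


# --- panel statistics -------------------------------------------------------


def random_match_probability(genotype_freqs: np.ndarray) -> float:
    """Probability two unrelated samples share the full barcode.

    *genotype_freqs* is an (n_loci, 3) array of per-locus (HOM1, HET, HOM2)
    genotype frequencies; independent loci give
    ``p = prod_i sum_j g_ij**2``.
    """
    g = np.asarray(genotype_freqs, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3 or (g < 0).any():
        raise ValueError("genotype_freqs must be (n_loci, 3) with entries >= 0")
    if not np.allclose(g.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each locus's genotype frequencies must sum to 1")
    return float(np.prod((g**2).sum(axis=1)))


def hwe_genotype_freqs(p: float, n_loci: int) -> np.ndarray:
    """(n_loci, 3) HWE genotype frequencies at allele-1 frequency *p*."""
    return np.tile([p**2, 2 * p * (1 - p), (1 - p) ** 2], (n_loci, 1))


def collision_probability(p: float, n_samples: int) -> float:
    """Birthday bound: probability any two of *n_samples* barcodes collide.

    ``1 - (1-p)**C(n,2)``, evaluated in log1p form so tiny p stays accurate.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if n_samples <= 1 or p == 0.0:
        return 0.0
    pairs = math.comb(n_samples, 2)
    return -math.expm1(pairs * math.log1p(-p))


@dataclass(slots=True)
class PowerSimConfig:
    """Detection-limit simulation: contaminate one HWE reference with another
    at each fraction, run the integrated detector, record the detection rate."""

    fractions: tuple[float, ...] = (1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32)
    replicates: int = 200
    n_loci: int = 32
    maf: float = 0.5
    power_target: float = 0.95
    max_false_positive_rate: float = 0.05
    biobank_size: int = 10_000
    seed: int = 0


@dataclass(slots=True)
class PanelPowerReport:
    per_locus_match_prob: np.ndarray
    pairwise_match_prob: float
    collision_prob: float
    biobank_size: int
    power_curve: dict[float, float]
    false_positive_rate: float
    detection_limit_fraction: float | None
    replicates: int
    assumptions: str = field(
        default="HWE genotypes at MAF 0.5 per locus (true panel frequencies unpublished)"
    )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pairwise_match_prob": self.pairwise_match_prob,
                    "collision_prob": self.collision_prob,
                    "biobank_size": self.biobank_size,
                    "power_curve": {str(k): v for k, v in self.power_curve.items()},
                    "false_positive_rate": self.false_positive_rate,
                    "detection_limit_fraction": self.detection_limit_fraction,
                    "replicates": self.replicates,
                    "assumptions": self.assumptions,
                },
                fh,
                indent=2,
            )


def detection_limit(
    config: PowerSimConfig,
    call_thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    detection: DetectionThresholds = DEFAULT_DETECTION,
) -> PanelPowerReport:
    """Simulate the panel's contamination detection limit.

    Two reference barcodes are drawn under HWE; for every mixture fraction,
    *replicates* trace sets of (1-f) reference + f contaminant are pushed
    through :func:`detect_contamination`, plus *replicates* pure-sample
    replicates for the false-positive rate.  The detection limit is the
    smallest fraction whose power meets ``power_target`` (None if the FPR
    bound fails).
    """
    rng = np.random.default_rng(config.seed)
    sim = SimulationConfig(
        n_loci=config.n_loci,
        allele_freqs=tuple([config.maf] * config.n_loci),
        seed=config.seed,
    )
    assays = default_panel(config.n_loci)
    host, contaminant = simulate_profiles(sim, 2, assays=assays, rng=rng)
    host.sample_id, contaminant.sample_id = "REF-A", "REF-B"
    registry = assign_references([host, contaminant], assays=assays)

    def _contaminated(traces) -> bool:
        report = detect_contamination(
            traces, host, registry,
            call_thresholds=call_thresholds, thresholds=detection,
            reference_id="REF-A",
        )
        return report.disposition is Disposition.CONTAMINATED

    power_curve: dict[float, float] = {}
    for f in sorted(config.fractions, reverse=True):
        contributors = tuple(
            (rid, frac)
            for rid, frac in (("REF-A", 1.0 - f), ("REF-B", f))
            if frac > 0
        )
        spec = MixtureSpec(contributors)
        hits = sum(
            _contaminated(simulate_mixture([host, contaminant], spec, sim, rng, assays))
            for _ in range(config.replicates)
        )
        power_curve[f] = hits / config.replicates
    false_pos = (
        sum(
            _contaminated(traces_for_profile(host, sim, rng, assays))
            for _ in range(config.replicates)
        )
        / config.replicates
    )

    limit: float | None = None
    if false_pos <= config.max_false_positive_rate:
        passing = [f for f, pw in power_curve.items() if pw >= config.power_target]
        limit = min(passing) if passing else None

    g = hwe_genotype_freqs(config.maf, config.n_loci)
    per_locus = (g**2).sum(axis=1)
    pairwise = random_match_probability(g)
    return PanelPowerReport(
        per_locus_match_prob=per_locus,
        pairwise_match_prob=pairwise,
        collision_prob=collision_probability(pairwise, config.biobank_size),
        biobank_size=config.biobank_size,
        power_curve=power_curve,
        false_positive_rate=false_pos,
        detection_limit_fraction=limit,
        replicates=config.replicates,
        assumptions=(
            f"HWE genotypes at MAF {config.maf} per locus "
            "(true panel frequencies unpublished)"
        ),
    )
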