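"""Seeded generators for every input the pipeline consumes.

All generators are deterministic given their seed and emit their ground
truth (loop sizes, planted folds, link counts) alongside the data, so tests
can close the loop between generation and estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromatid import ChromatidParams, CohesiveLinkSet
from .contacts import ContactMap, PsCurve

__all__ = [
    "G2Fixture",
    "exponential_loop_array",
    "make_g2_fixture",
    "make_compartment_labels",
    "make_cohesive_links",
    "make_target_ps",
    "make_planted_map",
    "planted_map_from_anchors",
]


def exponential_loop_array(genome_bp: float, mean_loop_bp: float,
                           seed: int | np.random.Generator = 0,
                           min_loop_bp: float = 2e4,
                           coverage: float = 1.0) -> np.ndarray:
    """Consecutive loop array with exponential size mix.

    Extrusion with stochastic loading produces approximately exponential
    loop sizes; this is the stand-in used when a 1D trajectory is not
    explicitly simulated. ``coverage`` < 1 interleaves unlooped linker
    stretches (early-prophase-like arrays with open gaps).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mean_gap_bp = mean_loop_bp * (1.0 - coverage) / coverage
    loops = []
    cursor = 0.0
    while cursor < genome_bp:
        size = max(rng.exponential(mean_loop_bp), min_loop_bp)
        end = min(cursor + size, genome_bp)
        loops.append((cursor, end))
        cursor = end
        if mean_gap_bp > 0:
            cursor += rng.exponential(mean_gap_bp)
    if len(loops) > 1 and loops[-1][1] - loops[-1][0] < min_loop_bp:
        a, _ = loops.pop()
        loops[-1] = (loops[-1][0], min(a + min_loop_bp, genome_bp))
    return np.array(loops, dtype=float)


@dataclass
class G2Fixture:
    """G2-like cohesin/CTCF landscape on a 1D lattice.

    CTCF sites carry motif orientations; extrusive cohesins are parked at
    convergent CTCF site pairs, which are the expected Hi-C dots. A/B
    compartment labels cover the lattice at ``label_bin_bp`` resolution.
    """

    lattice_length: int
    site_bp: int
    ctcf_sites: np.ndarray
    ctcf_orientations: list[str]
    anchored_cohesins: np.ndarray           # (n, 2) site pairs
    expected_dots_bp: np.ndarray            # (n, 2) bp anchor pairs
    ab_labels: list[str]
    label_bin_bp: int
    mean_loop_bp: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "lattice_length": int(self.lattice_length),
            "site_bp": int(self.site_bp),
            "ctcf_sites": [int(x) for x in self.ctcf_sites],
            "ctcf_orientations": list(self.ctcf_orientations),
            "anchored_cohesins": [[int(a), int(b)] for a, b in self.anchored_cohesins],
            "expected_dots_bp": [[float(a), float(b)] for a, b in self.expected_dots_bp],
            "ab_labels": list(self.ab_labels),
            "label_bin_bp": int(self.label_bin_bp),
            "mean_loop_bp": float(self.mean_loop_bp),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "G2Fixture":
        return cls(
            lattice_length=d["lattice_length"], site_bp=d["site_bp"],
            ctcf_sites=np.array(d["ctcf_sites"], dtype=int),
            ctcf_orientations=list(d["ctcf_orientations"]),
            anchored_cohesins=np.array(d["anchored_cohesins"], dtype=int).reshape(-1, 2),
            expected_dots_bp=np.array(d["expected_dots_bp"], dtype=float).reshape(-1, 2),
            ab_labels=list(d["ab_labels"]), label_bin_bp=d["label_bin_bp"],
            mean_loop_bp=d["mean_loop_bp"], seed=d["seed"],
        )


def make_g2_fixture(length_mb: float = 20.0, ctcf_spacing_kb: float = 100.0,
                    cohesin_density: float = 5.0, seed: int = 0,
                    site_bp: int = 1000, max_dot_separation_kb: float = 500.0,
                    label_bin_bp: int = 100_000,
                    compartment_domain_mb: float = 2.0) -> G2Fixture:
    """CTCF-anchored cohesin landscape with A/B labels.

    CTCF sites are placed with exponential spacing (mean ``ctcf_spacing_kb``)
    and random orientations; dots are expected at convergent (+ ... -)
    adjacent pairs closer than ``max_dot_separation_kb``. Cohesins (up to
    ``cohesin_density`` per Mb) are parked on those pairs.
    """
    if ctcf_spacing_kb * 1000 <= site_bp:
        raise ValueError("CTCF spacing must exceed the site size")
    rng = np.random.default_rng(seed)
    L = int(length_mb * 1e6 / site_bp)
    spacing_sites = ctcf_spacing_kb * 1000 / site_bp
    sites = []
    cursor = rng.exponential(spacing_sites)
    while cursor < L - 2:
        sites.append(int(cursor))
        cursor += max(rng.exponential(spacing_sites), 2)
    sites = np.array(sites, dtype=int)
    orientations = [str(rng.choice(["+", "-"])) for _ in sites]
    # convergent adjacent pairs within range
    pairs = []
    for i in range(len(sites) - 1):
        if orientations[i] == "+" and orientations[i + 1] == "-":
            if (sites[i + 1] - sites[i]) * site_bp <= max_dot_separation_kb * 1000:
                pairs.append((sites[i], sites[i + 1]))
    n_cohesin = int(cohesin_density * length_mb)
    if n_cohesin < len(pairs):
        keep = rng.choice(len(pairs), size=n_cohesin, replace=False)
        anchored = [pairs[k] for k in sorted(keep)]
    else:
        if n_cohesin > len(pairs):
            import warnings
            warnings.warn("cohesin density exceeds available convergent CTCF pairs")
        anchored = pairs
    anchored = np.array(anchored, dtype=int).reshape(-1, 2)
    dots_bp = anchored.astype(float) * site_bp
    n_bins = int(np.ceil(length_mb * 1e6 / label_bin_bp))
    labels = make_compartment_labels(
        n_bins, domain_length_bins=max(int(compartment_domain_mb * 1e6 / label_bin_bp), 1),
        seed=seed + 1,
    )
    mean_loop = float(np.mean(dots_bp[:, 1] - dots_bp[:, 0])) if len(dots_bp) else 0.0
    return G2Fixture(L, site_bp, sites, orientations, anchored, dots_bp,
                     labels, label_bin_bp, mean_loop, seed)


def make_compartment_labels(n_bins: int, domain_length_bins: int = 20,
                            seed: int = 0) -> list[str]:
    """Alternating A/B blocks with geometric lengths (mean domain size)."""
    if domain_length_bins >= n_bins:
        return ["A"] * n_bins
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    current = str(rng.choice(["A", "B"]))
    while len(labels) < n_bins:
        block = rng.geometric(1.0 / domain_length_bins)
        labels.extend([current] * block)
        current = "B" if current == "A" else "A"
    return labels[:n_bins]


def make_cohesive_links(length_mb: float, links_per_mb: float = 2.0,
                        seed: int = 0) -> CohesiveLinkSet:
    """Poisson-placed symmetric cohesive-cohesin tether positions."""
    if links_per_mb < 0:
        raise ValueError("links_per_mb must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(length_mb * links_per_mb)
    pos = np.sort(rng.uniform(0, length_mb * 1e6, size=n))
    return CohesiveLinkSet(pos)


def make_target_ps(params: ChromatidParams, noise_cv: float = 0.05,
                   seed: int = 0, genome_mb: float = 100.0,
                   replicates: int = 10, bins_per_decade: float = 25.0
                   ) -> PsCurve:
    """Simulated P(s) with multiplicative lognormal noise of given CV."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    from .fitting import simulate_ps
    ps = simulate_ps(params, genome_mb=genome_mb, replicates=replicates,
                     seed0=seed, bins_per_decade=bins_per_decade)
    if noise_cv == 0:
        return ps
    rng = np.random.default_rng(seed + 271828)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(ps.p))
    return PsCurve(ps.s_bp, ps.p * noise, ps.bins_per_decade)


def make_planted_map(n_bins: int = 200, bin_size: int = 100_000,
                     dots_bp: np.ndarray | None = None, dot_fold: float = 1.0,
                     ab_labels: list[str] | None = None,
                     compartment_fold: float = 1.0, seed: int = 0,
                     background_exponent: float = -1.0,
                     counts_scale: float = 2000.0) -> ContactMap:
    """Power-law background map with planted dot and compartment signal.

    The background follows P(s) ~ s^exponent (fractal-globule-like for
    exponent -1). Same-compartment bins are enriched by sqrt(fold) and
    cross-compartment bins depleted by sqrt(fold), so the within/between
    O/E ratio is the planted fold. Dots multiply a single bin pair by
    ``dot_fold``. Counts are Poisson-sampled, then symmetrized.
    """
    if dot_fold < 1 or compartment_fold < 1:
        raise ValueError("planted folds must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    with np.errstate(divide="ignore"):
        base = np.where(idx > 0, idx.astype(float) ** background_exponent, 0.0)
    mult = np.ones((n_bins, n_bins))
    if ab_labels is not None and compartment_fold > 1:
        lab = np.asarray(list(ab_labels))
        same = np.equal.outer(lab, lab)
        mult *= np.where(same, np.sqrt(compartment_fold),
                         1.0 / np.sqrt(compartment_fold))
    if dots_bp is not None and dot_fold > 1:
        for a_bp, b_bp in np.asarray(dots_bp, dtype=float).reshape(-1, 2):
            i, j = int(a_bp // bin_size), int(b_bp // bin_size)
            if 0 <= i < n_bins and 0 <= j < n_bins and i != j:
                mult[i, j] *= dot_fold
                mult[j, i] *= dot_fold
    lam = counts_scale * base * mult
    upper = np.triu(rng.poisson(lam), k=1)
    matrix = upper + upper.T
    return ContactMap(matrix.astype(float), bin_size, n_bins * bin_size)


def planted_map_from_anchors(anchor_pairs_bp: np.ndarray, length_bp: float,
                             bin_size: int = 100_000, dot_fold: float = 3.0,
                             seed: int = 0, **kwargs) -> ContactMap:
    """1D-to-map bridge: plant dots at currently anchored cohesin pairs.

    Used to score how each collision scenario erodes CTCF-CTCF dots: frames
    of a prophase trajectory are converted to maps whose dots sit wherever
    cohesins still bridge their CTCF anchors.
    """
    n_bins = int(np.ceil(length_bp / bin_size))
    return make_planted_map(n_bins=n_bins, bin_size=bin_size,
                            dots_bp=anchor_pairs_bp, dot_fold=dot_fold,
                            seed=seed, **kwargs)
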