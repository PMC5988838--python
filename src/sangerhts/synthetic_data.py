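"""Synthetic data generation for the Sanger-vs-metabarcoding concordance analysis.

Produces a panel of closely related reference haplotypes (full ITS1-5.8S-ITS2
amplicons differing only at a handful of diagnostic substitution sites), mixed
per-sample communities with a well-defined dominant member, multinomial HTS
read-count vectors, and mixed-template Sanger chromatograms whose per-position
peak heights are proportional to template abundances.

All randomness flows through :func:`numpy.random.default_rng` streams derived
deterministically from ``SimulationConfig.rng_seed``, so identical configs
reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from ._iupac import BASE_INDEX, PLAIN_BASES, is_plain

__all__ = [
    "OTUReference",
    "CommunityProfile",
    "Chromatogram",
    "SimulationConfig",
    "generate_otu_panel",
    "simulate_communities",
    "simulate_hts_counts",
    "simulate_chromatogram",
    "stage_rng",
    "CATEGORY_EDGES",
]

# Secondary-photobiont abundance categories, in percent of reads.
# Category 1 is exactly 0%; categories 2-5 are the half-open bins
# (0, 10], (10, 20], (20, 30], (30, 100].
CATEGORY_EDGES = (0.0, 10.0, 20.0, 30.0, 100.0)

_ANCHOR_LEN = 12
_HEAD_LEN = 20
_TAIL_LEN = 20


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream: one master seed, independent stages."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode("ascii"))])


@dataclass(frozen=True)
class OTUReference:
    """A known photobiont haplotype with ITS1/5.8S/ITS2 region coordinates.

    Spans are zero-based half-open intervals into ``sequence``, ordered
    ITS1 < 5.8S < ITS2 and pairwise disjoint.
    """

    otu_id: str
    sequence: str
    its1_span: tuple[int, int]
    r58s_span: tuple[int, int]
    its2_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not is_plain(self.sequence):
            raise ValueError(f"{self.otu_id}: reference sequence must be plain A/C/G/T")
        spans = (self.its1_span, self.r58s_span, self.its2_span)
        prev_end = 0
        for name, (start, end) in zip(("ITS1", "5.8S", "ITS2"), spans):
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"{self.otu_id}: {name} span {start, end} out of bounds")
            if start < prev_end:
                raise ValueError(f"{self.otu_id}: spans overlap or are out of order at {name}")
            prev_end = end

    def region(self, name: str) -> str:
        """Subsequence of one region; *name* in {'ITS1', '5.8S', 'ITS2', 'full_ITS'}."""
        if name == "full_ITS":
            return self.sequence
        span = {"ITS1": self.its1_span, "5.8S": self.r58s_span, "ITS2": self.its2_span}[name]
        return self.sequence[span[0] : span[1]]


@dataclass(frozen=True)
class CommunityProfile:
    """Ground-truth relative abundances of OTU haplotypes in one sample."""

    sample_id: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = list(self.fractions.values())
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"{self.sample_id}: fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: fractions must sum to 1 (got {sum(vals)})")
        nonzero = sorted((v for v in vals if v > 0), reverse=True)
        if len(nonzero) > 3:
            raise ValueError(f"{self.sample_id}: more than 3 members with nonzero abundance")
        if len(nonzero) >= 2 and nonzero[0] == nonzero[1]:
            raise ValueError(f"{self.sample_id}: tie for the dominant member")

    @property
    def dominant_otu(self) -> str:
        return max(self.fractions, key=lambda k: self.fractions[k])

    @property
    def secondary_fraction(self) -> float:
        ordered = sorted(self.fractions.values(), reverse=True)
        return ordered[1] if len(ordered) > 1 else 0.0


class Chromatogram:
    """Per-position fluorescence peak heights over the four bases.

    ``heights`` is a float array of shape (length, 4) with columns in A, C, G, T
    order; every position carries at least one strictly positive peak.
    """

    def __init__(self, heights: np.ndarray, sample_id: str = "", marker: str = "full_ITS"):
        heights = np.asarray(heights, dtype=float)
        if heights.ndim != 2 or heights.shape[1] != 4:
            raise ValueError("heights must have shape (length, 4)")
        if np.any(heights < 0):
            raise ValueError("peak heights must be nonnegative")
        if np.any(heights.max(axis=1) <= 0):
            raise ValueError("every position needs at least one positive peak")
        self.heights = heights
        self.sample_id = sample_id
        self.marker = marker

    def __len__(self) -> int:
        return self.heights.shape[0]

    def peak_heights(self, position: int) -> dict[str, float]:
        return {b: float(self.heights[position, i]) for b, i in BASE_INDEX.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated experiment (seeded, hence fully reproducible)."""

    n_otus: int = 6
    n_samples: int = 240
    n_variable_sites: int = 3
    hts_depth: int = 10_000
    #: design weights over the five secondary-abundance categories
    category_weights: tuple[float, ...] = (0.25, 0.30, 0.15, 0.15, 0.15)
    #: upper bound for the secondary fraction in category 5 (must stay < dominant)
    category5_max: float = 0.45
    #: probability that a mixed sample carries a third, rare member
    tertiary_prob: float = 0.05
    chromatogram_noise_sd: float = 0.05
    hts_error_rate: float = 0.0
    its1_length: int = 160
    r58s_length: int = 120
    its2_length: int = 180
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_samples < 0 or self.n_variable_sites < 1:
            raise ValueError("counts must be positive")
        if self.hts_depth < 0:
            raise ValueError("hts_depth must be nonnegative")
        if len(self.category_weights) != 5:
            raise ValueError("category_weights needs exactly 5 entries")
        if any(w < 0 for w in self.category_weights) or sum(self.category_weights) <= 0:
            raise ValueError("category_weights must be nonnegative and not all zero")
        if not (0 < self.category5_max < 0.5):
            raise ValueError("category5_max must lie in (0.30, 0.50) territory below 0.5")
        if not (0 <= self.tertiary_prob < 1):
            raise ValueError("tertiary_prob must lie in [0, 1)")
        if self.chromatogram_noise_sd < 0:
            raise ValueError("chromatogram_noise_sd must be >= 0")
        if not (0 <= self.hts_error_rate < 1):
            raise ValueError("hts_error_rate must lie in [0, 1)")

    @property
    def sequence_length(self) -> int:
        return (
            _HEAD_LEN + _TAIL_LEN + 4 * _ANCHOR_LEN
            + self.its1_length + self.r58s_length + self.its2_length
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(PLAIN_BASES[i] for i in rng.integers(0, 4, size=length))


def _per_otu_site_count(config: SimulationConfig) -> int:
    """Private substitutions per OTU per region.

    Sized so that pairwise panel identity lands strictly inside (95%, 99%):
    distinct OTUs carry disjoint private sites, so any pair differs at
    ``2 * m`` positions per region and ``4 * m`` overall.
    """
    length = config.sequence_length
    # > 1% divergence: 4m > 0.01 * L
    m_min = int(np.floor(0.01 * length / 4)) + 1
    return max(config.n_variable_sites, m_min)


def generate_otu_panel(config: SimulationConfig) -> list[OTUReference]:
    """Build ``n_otus`` pre-aligned references from one ancestral amplicon.

    Every OTU receives a disjoint set of private substitutions inside ITS1 and
    inside ITS2 (anchors, flanks and 5.8S stay conserved), so all pairs differ
    at >= ``n_variable_sites`` diagnostic sites per spacer while full-length
    identity stays within the mutually comparable (95%, 99%) band.
    """
    if config.n_otus < 2:
        raise ValueError("a panel needs at least 2 OTUs")
    m = _per_otu_site_count(config)
    length = config.sequence_length
    if 4 * m > 0.05 * length:
        raise ValueError(
            f"infeasible: {m} private sites per OTU per region would push pairwise "
            f"identity below 95% for length {length}"
        )
    for region_len, name in ((config.its1_length, "ITS1"), (config.its2_length, "ITS2")):
        if config.n_otus * m > region_len:
            raise ValueError(
                f"infeasible: {config.n_otus} OTUs x {m} private sites exceed the "
                f"{region_len}-nt {name} region"
            )

    rng = stage_rng(config.rng_seed, "panel")
    for _ in range(100):
        head = _random_seq(rng, _HEAD_LEN)
        m1 = _random_seq(rng, _ANCHOR_LEN)
        its1 = _random_seq(rng, config.its1_length)
        m2 = _random_seq(rng, _ANCHOR_LEN)
        r58s = _random_seq(rng, config.r58s_length)
        m3 = _random_seq(rng, _ANCHOR_LEN)
        its2 = _random_seq(rng, config.its2_length)
        m4 = _random_seq(rng, _ANCHOR_LEN)
        tail = _random_seq(rng, _TAIL_LEN)
        ancestral = head + m1 + its1 + m2 + r58s + m3 + its2 + m4 + tail

        its1_start = _HEAD_LEN + _ANCHOR_LEN
        its1_end = its1_start + config.its1_length
        r58s_start = its1_end + _ANCHOR_LEN
        r58s_end = r58s_start + config.r58s_length
        its2_start = r58s_end + _ANCHOR_LEN
        its2_end = its2_start + config.its2_length

        its1_sites = rng.choice(config.its1_length, size=config.n_otus * m, replace=False)
        its2_sites = rng.choice(config.its2_length, size=config.n_otus * m, replace=False)

        panel: list[OTUReference] = []
        for k in range(config.n_otus):
            seq = list(ancestral)
            for local in list(its1_sites[k * m : (k + 1) * m]):
                pos = its1_start + int(local)
                seq[pos] = rng.choice([b for b in PLAIN_BASES if b != ancestral[pos]])
            for local in list(its2_sites[k * m : (k + 1) * m]):
                pos = its2_start + int(local)
                seq[pos] = rng.choice([b for b in PLAIN_BASES if b != ancestral[pos]])
            panel.append(
                OTUReference(
                    otu_id=f"OTU{k + 1}",
                    sequence="".join(seq),
                    its1_span=(its1_start, its1_end),
                    r58s_span=(r58s_start, r58s_end),
                    its2_span=(its2_start, its2_end),
                )
            )

        # anchors must stay unique within every reference, else region
        # extraction is ill-defined; collisions are astronomically rare
        if all(
            ref.sequence.count(motif) == 1
            for ref in panel
            for motif in (m1, m2, m3, m4)
        ):
            return panel
    raise RuntimeError("could not generate a panel with unique anchor motifs")


def _draw_category(rng: np.random.Generator, weights: np.ndarray) -> int:
    return int(rng.choice(5, p=weights)) + 1


def _draw_secondary_fraction(rng: np.random.Generator, category: int, cat5_max: float) -> float:
    """Secondary fraction consistent with the half-open category bins."""
    if category == 1:
        return 0.0
    lo, hi = {
        2: (0.0, 0.10),
        3: (0.10, 0.20),
        4: (0.20, 0.30),
        5: (0.30, cat5_max),
    }[category]
    # uniform on (lo, hi]
    return hi - rng.uniform(0.0, hi - lo)


def simulate_communities(
    panel: list[OTUReference],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[CommunityProfile]:
    """Draw ``n_samples`` mixed communities over the panel.

    The dominant OTU cycles through the panel (every OTU is predominant
    somewhere once ``n_samples >= n_otus``); the secondary fraction is drawn
    from the configured category design; a small tertiary member is added with
    probability ``tertiary_prob`` in mixed samples, kept strictly below the
    secondary fraction so the abundance ranking is unambiguous.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if rng is None:
        rng = stage_rng(config.rng_seed, "communities")
    weights = np.asarray(config.category_weights, dtype=float)
    weights = weights / weights.sum()
    otu_ids = [ref.otu_id for ref in panel]

    profiles: list[CommunityProfile] = []
    for i in range(config.n_samples):
        dominant = otu_ids[i % len(otu_ids)]
        for _ in range(1000):
            category = _draw_category(rng, weights)
            fractions = {dominant: 1.0}
            if category > 1 and len(otu_ids) > 1:
                f2 = _draw_secondary_fraction(rng, category, config.category5_max)
                others = [o for o in otu_ids if o != dominant]
                secondary = others[int(rng.integers(len(others)))]
                fractions = {dominant: 1.0 - f2, secondary: f2}
                if len(others) > 1 and rng.uniform() < config.tertiary_prob:
                    f3 = rng.uniform(0.0, f2 / 2)
                    if f3 > 0:
                        rest = [o for o in others if o != secondary]
                        tertiary = rest[int(rng.integers(len(rest)))]
                        fractions = {dominant: 1.0 - f2 - f3, secondary: f2, tertiary: f3}
            ordered = sorted(fractions.values(), reverse=True)
            if len(ordered) == 1 or ordered[0] > ordered[1]:  # unique dominant only
                break
        else:  # pragma: no cover - unreachable with category5_max < 0.5
            raise RuntimeError("could not draw a community with a unique dominant member")
        profiles.append(CommunityProfile(sample_id=f"S{i + 1:04d}", fractions=fractions))
    return profiles


def simulate_hts_counts(
    profile: CommunityProfile,
    panel: list[OTUReference],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multinomial read counts over the panel for one sample.

    ``hts_error_rate`` acts at the count level as a symmetric cross-assignment
    probability: a fraction of reads is redistributed uniformly over the other
    panel members (panel OTUs are equidistant by construction). Counts always
    sum to ``hts_depth``.
    """
    if config.hts_depth <= 0:
        raise ValueError("hts_depth must be > 0 to draw reads")
    if rng is None:
        rng = stage_rng(config.rng_seed, "hts")
    unknown = set(profile.fractions) - {ref.otu_id for ref in panel}
    if unknown:
        raise ValueError(f"profile references unknown OTUs: {sorted(unknown)}")
    p = np.array([profile.fractions.get(ref.otu_id, 0.0) for ref in panel])
    e = config.hts_error_rate
    if e > 0 and len(panel) > 1:
        k = len(panel)
        cross = (p.sum() - p) / (k - 1)
        p = (1 - e) * p + e * cross
    p = p / p.sum()
    return rng.multinomial(config.hts_depth, p)


def simulate_chromatogram(
    profile: CommunityProfile,
    panel: list[OTUReference],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    marker: str = "full_ITS",
) -> Chromatogram:
    """Mix template haplotypes into one chromatogram, peak heights ∝ abundance.

    At position i the height of base b is ``sum_t fraction_t * [t has b at i]``
    times a multiplicative noise factor ``1 + Normal(0, noise_sd)`` (clipped at
    zero). With noise 0 the mixing is exact. ``marker`` selects the template:
    the full amplicon, or the ITS2 region plus its two flanking anchors.
    """
    by_id = {ref.otu_id: ref for ref in panel}
    unknown = [o for o, f in profile.fractions.items() if f > 0 and o not in by_id]
    if unknown:
        raise ValueError(f"profile references unknown OTUs: {sorted(unknown)}")

    templates: list[tuple[str, float]] = []
    for otu_id, frac in profile.fractions.items():
        if frac <= 0:
            continue
        ref = by_id[otu_id]
        if marker == "full_ITS":
            seq = ref.sequence
        elif marker == "ITS2_only":
            start, end = ref.its2_span
            seq = ref.sequence[start - _ANCHOR_LEN : end + _ANCHOR_LEN]
        else:
            raise ValueError(f"unknown marker {marker!r}")
        templates.append((seq, frac))
    lengths = {len(seq) for seq, _ in templates}
    if len(lengths) != 1:
        raise ValueError("all templates must have equal length (pre-aligned panel)")
    (length,) = lengths

    heights = np.zeros((length, 4))
    for seq, frac in templates:
        idx = np.fromiter((BASE_INDEX[c] for c in seq), dtype=np.intp, count=length)
        heights[np.arange(length), idx] += frac
    if config.chromatogram_noise_sd > 0:
        if rng is None:
            rng = stage_rng(config.rng_seed, "chromatograms")
        heights = heights * (1.0 + rng.normal(0.0, config.chromatogram_noise_sd, heights.shape))
        heights = np.clip(heights, 0.0, None)
    return Chromatogram(heights, sample_id=profile.sample_id, marker=marker)
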