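"""Sanger base calling, quality control and region extraction.

Base calling applies the classic secondary-peak rule: at each trace position
the call is ambiguous when the second-highest peak exceeds a fixed fraction
(default 25%) of the highest peak, in which case the IUPAC code covering every
base above that fraction is emitted. QC rejects sequences containing any
ambiguous call (configurable) or that are substantially truncated. ITS1/ITS2
subregions are cut out between conserved anchor motifs shared by the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._iupac import BASE_INDEX, PLAIN_BASES, bases_of, code_for
from .synthetic_data import Chromatogram, OTUReference

__all__ = [
    "CalledSequence",
    "RegionAnchors",
    "RegionExtractionError",
    "call_bases",
    "qc_sequence",
    "extract_regions",
    "anchors_from_panel",
]


@dataclass(frozen=True)
class CalledSequence:
    """One base-called sequence with its ambiguity record and QC verdict."""

    sample_id: str
    marker: str  # full_ITS | ITS2_only | ITS1_only
    bases: str
    ambiguous_positions: tuple[int, ...] = ()
    qc_status: str = "pending"  # pending | pass | fail
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        expected = tuple(i for i, c in enumerate(self.bases) if c not in BASE_INDEX)
        if tuple(self.ambiguous_positions) != expected:
            raise ValueError("ambiguous_positions must index exactly the non-ACGT characters")
        if self.qc_status not in ("pending", "pass", "fail"):
            raise ValueError(f"invalid qc_status {self.qc_status!r}")

    def __len__(self) -> int:
        return len(self.bases)


# codes indexed by the 4-bit mask A=1, C=2, G=4, T=8
_MASK_TO_CODE = np.array(
    ["?"] + [code_for({b for b, i in BASE_INDEX.items() if mask >> i & 1})
             for mask in range(1, 16)]
)
_MASK_WEIGHTS = np.array([1, 2, 4, 8])


def call_bases(
    chromatogram: Chromatogram,
    secondary_peak_threshold: float = 0.25,
) -> CalledSequence:
    """Call one sequence from a chromatogram under the secondary-peak rule.

    At each position with peak heights h1 >= h2 >= ...: if h2/h1 exceeds the
    threshold, the IUPAC code for *all* bases whose peak exceeds
    ``threshold * h1`` is emitted (2-, 3- or 4-fold codes) and the position is
    recorded as ambiguous; otherwise the top base is called. Deterministic
    given the chromatogram.
    """
    if not (0 < secondary_peak_threshold < 1):
        raise ValueError("secondary_peak_threshold must lie in (0, 1)")
    h = chromatogram.heights
    h1 = h.max(axis=1)
    if np.any(h1 <= 0):
        raise ValueError("malformed chromatogram: position with no positive peak")
    above = h > secondary_peak_threshold * h1[:, None]
    # the maximal peak always survives its own threshold
    mask = above @ _MASK_WEIGHTS
    codes = _MASK_TO_CODE[mask]
    ambiguous = tuple(int(i) for i in np.flatnonzero(above.sum(axis=1) > 1))
    return CalledSequence(
        sample_id=chromatogram.sample_id,
        marker=chromatogram.marker,
        bases="".join(codes),
        ambiguous_positions=ambiguous,
    )


def qc_sequence(
    called: CalledSequence,
    expected_length: int | None = None,
    min_length_fraction: float = 0.9,
    qc_mode: str = "any_ambiguity",
    variable_positions: set[int] | None = None,
) -> CalledSequence:
    """Attach a pass/fail verdict to a called sequence.

    Fails with reason ``ambiguous_calls`` on any ambiguous position (default
    zero-tolerance; ``qc_mode='variable_sites'`` fails only when an ambiguity
    falls on a position in ``variable_positions``), and with reason
    ``truncated`` when shorter than ``min_length_fraction`` of
    ``expected_length``.
    """
    if not called.bases:
        raise ValueError("cannot QC an empty sequence")
    if qc_mode not in ("any_ambiguity", "variable_sites"):
        raise ValueError(f"unknown qc_mode {qc_mode!r}")
    offending = called.ambiguous_positions
    if qc_mode == "variable_sites":
        sites = variable_positions or set()
        offending = tuple(p for p in offending if p in sites)
    if offending:
        return replace(called, qc_status="fail", fail_reason="ambiguous_calls")
    if expected_length is not None and len(called) < min_length_fraction * expected_length:
        return replace(called, qc_status="fail", fail_reason="truncated")
    return replace(called, qc_status="pass", fail_reason=None)


@dataclass(frozen=True)
class RegionAnchors:
    """Conserved flanking motifs bounding the ITS1 and ITS2 regions."""

    its1_start_motif: str
    its1_end_motif: str
    its2_start_motif: str
    its2_end_motif: str


class RegionExtractionError(ValueError):
    """A bounding motif was absent or non-unique; the sequence must be flagged."""

    def __init__(self, region: str, motif: str, n_hits: int):
        self.region = region
        self.motif = motif
        self.n_hits = n_hits
        word = "missing" if n_hits == 0 else f"found {n_hits} times"
        super().__init__(f"{region} anchor motif {motif!r} {word}")


def _find_motif(seq: str, motif: str) -> list[int]:
    """IUPAC-aware exact search: an ambiguous sequence character matches a
    motif base when that base is in the character's set."""
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(motif[j] in bases_of(seq[i + j]) for j in range(len(motif))):
            hits.append(i)
    return hits


def _extract_between(seq: str, region: str, start_motif: str, end_motif: str
                     ) -> tuple[str, tuple[int, int]]:
    start_hits = _find_motif(seq, start_motif)
    if len(start_hits) != 1:
        raise RegionExtractionError(region, start_motif, len(start_hits))
    end_hits = _find_motif(seq, end_motif)
    if len(end_hits) != 1:
        raise RegionExtractionError(region, end_motif, len(end_hits))
    start = start_hits[0] + len(start_motif)
    end = end_hits[0]
    if end < start:
        raise RegionExtractionError(region, end_motif, 0)
    return seq[start:end], (start, end)


def extract_regions(
    called: CalledSequence,
    anchors: RegionAnchors,
    allow_unchecked: bool = False,
) -> dict[str, tuple[str, tuple[int, int]]]:
    """Cut the ITS1/ITS2 subregions out of a called sequence by anchor motifs.

    Returns a map region name -> (subsequence, (start, end)); for marker
    ``ITS2_only`` only ITS2 is extractable. Requires a QC-passed sequence
    unless ``allow_unchecked`` is set. Motif search is IUPAC-aware, so
    ambiguity codes inside a region (but not breaking a motif) are carried
    through to the extracted subsequence.
    """
    if called.qc_status != "pass" and not allow_unchecked:
        raise ValueError(
            f"{called.sample_id}: sequence did not pass QC "
            "(pass allow_unchecked=True to extract anyway)"
        )
    regions: dict[str, tuple[str, tuple[int, int]]] = {}
    if called.marker == "full_ITS":
        regions["ITS1"] = _extract_between(
            called.bases, "ITS1", anchors.its1_start_motif, anchors.its1_end_motif
        )
    regions["ITS2"] = _extract_between(
        called.bases, "ITS2", anchors.its2_start_motif, anchors.its2_end_motif
    )
    return regions


def anchors_from_panel(panel: list[OTUReference], anchor_length: int = 12) -> RegionAnchors:
    """Derive the shared flanking motifs from a pre-aligned reference panel.

    Takes ``anchor_length`` bases immediately outside each region span of the
    first reference and checks they are conserved (and unique) across the
    whole panel.
    """
    ref = panel[0]
    i1s, i1e = ref.its1_span
    i2s, i2e = ref.its2_span
    if i1s < anchor_length:
        raise ValueError("not enough flank upstream of ITS1 for an anchor")
    anchors = RegionAnchors(
        its1_start_motif=ref.sequence[i1s - anchor_length : i1s],
        its1_end_motif=ref.sequence[i1e : i1e + anchor_length],
        its2_start_motif=ref.sequence[i2s - anchor_length : i2s],
        its2_end_motif=ref.sequence[i2e : i2e + anchor_length],
    )
    for other in panel:
        for motif in (anchors.its1_start_motif, anchors.its1_end_motif,
                      anchors.its2_start_motif, anchors.its2_end_motif):
            if other.sequence.count(motif) != 1:
                raise ValueError(
                    f"anchor motif {motif!r} not unique/conserved in {other.otu_id}"
                )
    return anchors
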