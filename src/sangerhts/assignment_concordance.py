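"""Sequence-to-OTU assignment, abundance categories and concordance statistics.

The assignment criteria mirror a best-hit identity search against the panel of
OTU representative sequences: hits below a 95% identity floor are discarded, a
sequence is assigned only when its best hit reaches 99% identity, is strictly
unique, and clears the second-best hit by a configurable margin. Identity is
computed by affine-gap global (Needleman-Wunsch/Gotoh) alignment — query and
references cover the same marker region at near-full length, so global and
local identity coincide and no external search binary is needed.

Also provides the five secondary-abundance categories, the per-category
success summary (stacked-bar-ready), abundance-sorted greedy clustering at an
identity threshold, and the ITS1-vs-ITS2 resolution comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._iupac import BASE_INDEX, bases_of, is_plain
from .sanger import CalledSequence
from .synthetic_data import CATEGORY_EDGES, OTUReference

__all__ = [
    "AssignmentResult",
    "CategoryRecord",
    "ConcordanceSummary",
    "Cluster",
    "ResolutionSummary",
    "align_global",
    "pairwise_identity",
    "assign_to_otu",
    "categorize_sample",
    "concordance_table",
    "greedy_cluster",
    "resolution_comparison",
]

# Alignment scoring: match +1, mismatch -1; a gap of length L costs
# gap_open + (L - 1) * gap_extend.
MATCH = 1
MISMATCH = -1
GAP_OPEN = 2
GAP_EXTEND = 1
_NEG = np.int64(-(10**9))


def _query_match_matrix(query: str, subject: str) -> np.ndarray:
    """Boolean (len(query), len(subject)): IUPAC query char covers subject base."""
    if not is_plain(subject):
        raise ValueError("subject sequence must be plain A/C/G/T")
    sub_idx = np.fromiter((BASE_INDEX[c] for c in subject), dtype=np.intp, count=len(subject))
    rows = np.empty((len(query), len(subject)), dtype=bool)
    cover_cache: dict[str, np.ndarray] = {}
    for i, c in enumerate(query):
        cov = cover_cache.get(c)
        if cov is None:
            bases = bases_of(c)
            cov = np.array([b in bases for b in "ACGT"])
            cover_cache[c] = cov
        rows[i] = cov[sub_idx]
    return rows


def align_global(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Affine-gap global alignment; returns (score, matched columns, columns).

    ``seq_a`` is the query and may contain IUPAC ambiguity codes (a code
    matches a subject base iff the base is in its set); ``seq_b`` must be
    plain A/C/G/T. Gap columns count toward the total. Traceback ties are
    broken by preferring diagonal, then up (gap in the subject), then left.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    match = _query_match_matrix(seq_a, seq_b)
    n, m = match.shape

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (left moves)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in subject (up moves)
    M[0, 0] = 0
    j = np.arange(1, m + 1)
    Ix[0, 1:] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    i = np.arange(1, n + 1)
    Iy[1:, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)

    ext_ramp = GAP_EXTEND * np.arange(m + 1, dtype=np.int64)
    for r in range(1, n + 1):
        s = np.where(match[r - 1], MATCH, MISMATCH)
        diag = np.maximum(np.maximum(M[r - 1, :-1], Ix[r - 1, :-1]), Iy[r - 1, :-1])
        M[r, 1:] = diag + s
        Iy[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], Ix[r - 1, 1:]) - GAP_OPEN,
            Iy[r - 1, 1:] - GAP_EXTEND,
        )
        # left gaps within the row: running-max prefix scan over max(M, Iy)
        best = np.maximum(M[r], Iy[r]) + ext_ramp
        run = np.maximum.accumulate(best)[:-1]
        Ix[r, 1:] = run - GAP_OPEN - ext_ramp[:-1]

    # traceback; state preference on ties: diagonal (M), then up (Iy), then left (Ix)
    r, c = n, m
    finals = (M[r, c], Iy[r, c], Ix[r, c])
    score = int(max(finals))
    state = ("M", "Iy", "Ix")[int(np.argmax(finals))]
    matched = 0
    columns = 0
    while r > 0 or c > 0:
        columns += 1
        if state == "M":
            if match[r - 1, c - 1]:
                matched += 1
            target = M[r, c] - (MATCH if match[r - 1, c - 1] else MISMATCH)
            r, c = r - 1, c - 1
            if M[r, c] == target:
                state = "M"
            elif Iy[r, c] == target:
                state = "Iy"
            else:
                state = "Ix"
        elif state == "Iy":  # consumed a query base against a gap
            val = Iy[r, c]
            r = r - 1
            if M[r, c] - GAP_OPEN == val:
                state = "M"
            elif Iy[r, c] - GAP_EXTEND == val:
                state = "Iy"
            else:
                state = "Ix"
        else:  # Ix: consumed a subject base against a gap
            val = Ix[r, c]
            c = c - 1
            if M[r, c] - GAP_OPEN == val:
                state = "M"
            elif Iy[r, c] - GAP_OPEN == val:
                state = "Iy"
            else:
                state = "Ix"
        if r == 0 and c == 0:
            break
        if r == 0:
            state = "Ix"
        elif c == 0:
            state = "Iy"
    return score, matched, columns


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and alignment length under affine-gap global alignment.

    Identity = matched columns / aligned columns x 100 (gap columns in the
    denominator); see :func:`align_global` for the scoring scheme and the
    IUPAC handling of the query.
    """
    _, matched, columns = align_global(seq_a, seq_b)
    return 100.0 * matched / columns, columns


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of matching one called sequence against the OTU panel."""

    sample_id: str
    marker: str
    best_otu: str | None
    best_identity: float | None
    second_best_identity: float | None
    status: str  # assigned | tie_at_top | below_floor | no_clear_best | qc_failed

    def __post_init__(self) -> None:
        if self.status == "assigned":
            if self.best_otu is None or self.best_identity is None:
                raise ValueError("assigned result needs a best hit")
        if (
            self.best_identity is not None
            and self.second_best_identity is not None
            and self.second_best_identity > self.best_identity + 1e-12
        ):
            raise ValueError("second-best identity exceeds best identity")


def _panel_region(ref: OTUReference, marker: str) -> str:
    if marker == "full_ITS":
        return ref.sequence
    if marker == "ITS2_only":
        return ref.region("ITS2")
    if marker == "ITS1_only":
        return ref.region("ITS1")
    raise ValueError(f"unknown marker {marker!r}")


def assign_to_otu(
    called: CalledSequence,
    panel: list[OTUReference],
    floor: float = 95.0,
    accept: float = 99.0,
    margin: float = 0.5,
) -> AssignmentResult:
    """Assign a called sequence to the best-matching panel OTU.

    Status is ``assigned`` iff the best identity reaches ``accept``, the best
    hit is strictly unique, and best - second_best >= ``margin`` percentage
    points; ``tie_at_top`` when two hits share the maximum; ``below_floor``
    when no hit reaches ``floor``; ``no_clear_best`` otherwise. QC-failed
    inputs short-circuit to ``qc_failed``.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if called.qc_status != "pass":
        return AssignmentResult(called.sample_id, called.marker, None, None, None, "qc_failed")
    identities = [
        (pairwise_identity(called.bases, _panel_region(ref, called.marker))[0], ref.otu_id)
        for ref in panel
    ]
    identities.sort(key=lambda t: -t[0])
    best_id, best_otu = identities[0]
    second_id = identities[1][0] if len(identities) > 1 else None

    if second_id is not None and second_id == best_id:
        status = "tie_at_top"
        best_otu = None
    elif best_id < floor:
        status = "below_floor"
        best_otu = None
    elif best_id < accept or (second_id is not None and second_id >= floor
                              and best_id - second_id < margin):
        status = "no_clear_best"
        best_otu = None
    else:
        status = "assigned"
    return AssignmentResult(called.sample_id, called.marker, best_otu, best_id, second_id, status)


@dataclass(frozen=True)
class CategoryRecord:
    """A sample's secondary-photobiont abundance category (1-5)."""

    sample_id: str
    category: int
    secondary_fraction: float  # percent
    dominant_otu: str


def categorize_sample(
    fractions: dict[str, float] | pd.Series,
    sample_id: str = "",
) -> CategoryRecord:
    """Classify a relative-abundance row into the five categories.

    Bins on the second-largest fraction (in percent): exactly 0 -> 1,
    (0, 10] -> 2, (10, 20] -> 3, (20, 30] -> 4, (30, 100] -> 5. The dominant
    OTU must be strictly unique.
    """
    if isinstance(fractions, pd.Series):
        sample_id = sample_id or str(fractions.name)
        fractions = fractions.to_dict()
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{sample_id}: fractions must sum to 1 (got {total})")
    ranked = sorted(fractions.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        raise ValueError(f"{sample_id}: tie for the dominant OTU")
    secondary_pct = ranked[1][1] * 100.0 if len(ranked) > 1 else 0.0
    if secondary_pct == 0.0:
        category = 1
    else:
        category = 2 + int(np.searchsorted(CATEGORY_EDGES[1:-1], secondary_pct, side="left"))
    return CategoryRecord(sample_id, category, secondary_pct, ranked[0][0])


@dataclass
class ConcordanceSummary:
    """Per-marker and per-category success statistics plus a plot-ready table."""

    per_marker: pd.DataFrame  # index marker; n_total, n_pass_qc, n_assigned, success_rate
    per_category: pd.DataFrame  # index (marker, category); n_pass, n_fail, proportion_pass
    concordant_fraction: dict[str, float | None]  # marker -> fraction (None if no assignments)
    long_table: pd.DataFrame  # marker, category, outcome, count, proportion
    unmatched_samples: list[str] = field(default_factory=list)

    def success_rate(self, marker: str) -> float:
        return float(self.per_marker.loc[marker, "success_rate"])

    def category_pass_percent(self, marker: str, category: int) -> float:
        return float(self.per_category.loc[(marker, category), "proportion_pass"]) * 100.0


def concordance_table(
    assignments: list[AssignmentResult],
    categories: list[CategoryRecord],
    qc: list[CalledSequence],
) -> ConcordanceSummary:
    """Join QC, assignment and category records into the success summary.

    Per marker: ``success_rate`` = sequences that passed QC *and* were
    assigned, over all sequenced samples, x100. Per (marker, category): the
    stacked pass/fail proportions where "pass" means the Sanger sequence
    passed QC. ``concordant_fraction`` is, among assigned sequences, the
    share whose best OTU equals the sample's dominant HTS OTU. Samples
    present in one input but not another are excluded and reported in
    ``unmatched_samples``.
    """
    qc_df = pd.DataFrame(
        [(s.sample_id, s.marker, s.qc_status) for s in qc],
        columns=["sample_id", "marker", "qc_status"],
    )
    if qc_df.duplicated(["sample_id", "marker"]).any():
        raise ValueError("duplicate (sample, marker) in QC records")
    asg_df = pd.DataFrame(
        [(a.sample_id, a.marker, a.status, a.best_otu) for a in assignments],
        columns=["sample_id", "marker", "status", "best_otu"],
    )
    cat_df = pd.DataFrame(
        [(c.sample_id, c.category, c.dominant_otu) for c in categories],
        columns=["sample_id", "category", "dominant_otu"],
    )

    joined = qc_df.merge(asg_df, on=["sample_id", "marker"], how="left")
    joined = joined.merge(cat_df, on="sample_id", how="left")
    unmatched = sorted(joined.loc[joined["category"].isna(), "sample_id"].unique())
    joined = joined.dropna(subset=["category"]).copy()
    joined["category"] = joined["category"].astype(int)
    joined["passed_qc"] = joined["qc_status"] == "pass"
    joined["assigned"] = joined["status"] == "assigned"

    per_marker = joined.groupby("marker").agg(
        n_total=("sample_id", "size"),
        n_pass_qc=("passed_qc", "sum"),
        n_assigned=("assigned", "sum"),
    )
    per_marker["success_rate"] = (
        100.0 * (joined["passed_qc"] & joined["assigned"]).groupby(joined["marker"]).sum()
        / per_marker["n_total"]
    )

    per_category = joined.groupby(["marker", "category"]).agg(
        n_pass=("passed_qc", "sum"),
        n_fail=("passed_qc", lambda s: int((~s).sum())),
    )
    per_category["proportion_pass"] = per_category["n_pass"] / (
        per_category["n_pass"] + per_category["n_fail"]
    )

    concordant: dict[str, float | None] = {}
    for marker, grp in joined.groupby("marker"):
        assigned = grp[grp["assigned"]]
        if len(assigned) == 0:
            concordant[str(marker)] = None
        else:
            concordant[str(marker)] = float(
                (assigned["best_otu"] == assigned["dominant_otu"]).mean()
            )

    rows = []
    for (marker, category), row in per_category.iterrows():
        total = row["n_pass"] + row["n_fail"]
        for outcome, count in (("pass", row["n_pass"]), ("fail", row["n_fail"])):
            rows.append(
                {
                    "marker": marker,
                    "category": category,
                    "outcome": outcome,
                    "count": int(count),
                    "proportion": count / total if total else np.nan,
                }
            )
    long_table = pd.DataFrame(rows, columns=["marker", "category", "outcome", "count", "proportion"])
    return ConcordanceSummary(per_marker, per_category, concordant, long_table, unmatched)


@dataclass
class Cluster:
    centroid_index: int
    centroid: str
    member_indices: list[int]


def greedy_cluster(
    seqs: list[str],
    abundances: list[float] | None = None,
    identity_threshold: float = 99.0,
) -> list[Cluster]:
    """Abundance-sorted greedy centroid clustering at an identity threshold.

    Sequences are visited by decreasing abundance (stable on ties); each joins
    the first existing centroid it matches at >= ``identity_threshold``
    percent identity, otherwise it founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if abundances is None:
        abundances = [1.0] * len(seqs)
    if len(abundances) != len(seqs):
        raise ValueError("abundances must align with seqs")
    order = sorted(range(len(seqs)), key=lambda i: (-abundances[i], i))
    clusters: list[Cluster] = []
    for idx in order:
        for cluster in clusters:
            identity, _ = pairwise_identity(seqs[idx], cluster.centroid)
            if identity >= identity_threshold:
                cluster.member_indices.append(idx)
                break
        else:
            clusters.append(Cluster(idx, seqs[idx], [idx]))
    return clusters


@dataclass
class ResolutionSummary:
    """Per-sample three-way ITS1 / ITS2 / dominant-HTS-OTU agreement."""

    table: pd.DataFrame  # sample_id, its1_otu, its2_otu, dominant_otu, three_way_match
    n_complete: int
    n_incomplete: int
    match_fraction: float | None  # None (undefined) when no sample has both assignments


def resolution_comparison(
    its1_assignments: list[AssignmentResult],
    its2_assignments: list[AssignmentResult],
    dominant_otus: dict[str, str],
) -> ResolutionSummary:
    """Compare OTU assignments from ITS1 against ITS2 and the HTS dominant OTU.

    Samples assigned for only one marker are counted as incomplete and
    excluded from the match fraction; an empty overlap yields an undefined
    (None) fraction rather than 0.
    """
    its1 = {a.sample_id: a.best_otu for a in its1_assignments if a.status == "assigned"}
    its2 = {a.sample_id: a.best_otu for a in its2_assignments if a.status == "assigned"}
    samples = sorted(set(its1) | set(its2))
    rows = []
    for s in samples:
        o1, o2 = its1.get(s), its2.get(s)
        dom = dominant_otus.get(s)
        complete = o1 is not None and o2 is not None
        rows.append(
            {
                "sample_id": s,
                "its1_otu": o1,
                "its2_otu": o2,
                "dominant_otu": dom,
                "three_way_match": bool(o1 == o2 == dom) if complete else None,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "its1_otu", "its2_otu", "dominant_otu", "three_way_match"]
    )
    complete = table["three_way_match"].notna()
    n_complete = int(complete.sum())
    fraction = float(table.loc[complete, "three_way_match"].mean()) if n_complete else None
    return ResolutionSummary(table, n_complete, int((~complete).sum()), fraction)


def plot_category_success(long_table: pd.DataFrame, path: str) -> None:
    """Render the stacked per-category pass/fail bar chart to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = sorted(long_table["marker"].unique())
    fig, axes = plt.subplots(1, len(markers), figsize=(4 * len(markers), 3.5), squeeze=False)
    for ax, marker in zip(axes[0], markers):
        sub = long_table[long_table["marker"] == marker]
        cats = sorted(sub["category"].unique())
        passes = [
            float(sub[(sub["category"] == c) & (sub["outcome"] == "pass")]["proportion"].sum())
            for c in cats
        ]
        fails = [1.0 - p for p in passes]
        ax.bar(cats, passes, color="#4c9f70", label="pass")
        ax.bar(cats, fails, bottom=passes, color="#c44e52", label="fail")
        ax.set_xlabel("secondary-abundance category")
        ax.set_ylabel("proportion of samples")
        ax.set_title(marker)
        ax.set_xticks(cats)
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
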