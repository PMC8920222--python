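"""Signed multi-omics overlap and gene-set over-representation.

Each exposure condition yields lists of significantly deregulated
identifiers (transcripts and/or proteins) with a direction of change.
This module merges the two molecular layers per condition, classifies the
overlap between two conditions into concordantly up-, concordantly down-
and contra-regulated identifiers, and tests user-supplied gene sets for
over-representation with a one-sided Fisher exact (hypergeometric tail)
test followed by Benjamini-Hochberg FDR control.

Identifier matching is case-insensitive exact symbol matching: symbols
are canonicalised to upper case on construction.  The background universe
for enrichment must be given explicitly (typically all quantified
identifiers); there is no hidden genome-wide default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DeregEntry",
    "DeregulationList",
    "OverlapResult",
    "GeneSet",
    "EnrichmentRow",
    "merge_layers",
    "classify_overlap",
    "fisher_enrichment",
    "bh_fdr",
    "compare_enrichment",
]

Layer = Literal["transcript", "protein", "merged"]


@dataclass(frozen=True)
class DeregEntry:
    """One deregulated identifier with its direction (+1 up / -1 down).

    When a log-ratio magnitude is supplied without an explicit direction,
    the direction is derived from its sign; an explicit direction that
    contradicts the magnitude's sign wins, with a warning.
    """

    identifier: str
    direction: int = 0
    magnitude: float | None = None
    conflict: bool = False  # set when the two layers disagreed at merge

    def __post_init__(self) -> None:
        object.__setattr__(self, "identifier", self.identifier.strip().upper())
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        direction = self.direction
        if direction == 0:
            if self.magnitude is None or self.magnitude == 0:
                raise ValueError(
                    f"{self.identifier}: need a direction or a signed magnitude"
                )
            direction = 1 if self.magnitude > 0 else -1
        elif direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {direction}")
        elif self.magnitude not in (None, 0):
            derived = 1 if self.magnitude > 0 else -1
            if derived != direction:
                warnings.warn(
                    f"{self.identifier}: explicit direction {direction:+d} "
                    f"contradicts magnitude sign; keeping the explicit direction",
                    stacklevel=2,
                )
        object.__setattr__(self, "direction", direction)


@dataclass(frozen=True)
class DeregulationList:
    """A condition's list of deregulated identifiers for one molecular layer."""

    condition: str
    layer: Layer
    entries: tuple[DeregEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.identifier for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers in list: {dupes}")

    @property
    def directions(self) -> dict[str, int]:
        return {e.identifier: e.direction for e in self.entries}

    @property
    def identifiers(self) -> frozenset[str]:
        return frozenset(e.identifier for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, condition: str, layer: Layer,
                   pairs: Iterable[tuple[str, int]]) -> "DeregulationList":
        return cls(condition, layer,
                   tuple(DeregEntry(i, d) for i, d in pairs))


@dataclass(frozen=True)
class OverlapResult:
    """Signed partition of the identifiers two conditions share."""

    common_ids: frozenset[str]
    n_up_both: int
    n_down_both: int
    n_contra: int
    n_unique_a: int
    n_unique_b: int
    up_both: frozenset[str] = field(default_factory=frozenset)
    down_both: frozenset[str] = field(default_factory=frozenset)
    contra: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class GeneSet:
    """A named pathway / gene-set with its member symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(m.strip().upper() for m in self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's over-representation result."""

    set_name: str
    set_size: int      # members inside the universe
    hits: int
    hit_ids: frozenset[str]
    p_value: float
    fdr: float


def merge_layers(transcripts: DeregulationList,
                 proteins: DeregulationList) -> DeregulationList:
    """Union of a condition's transcript and protein deregulation lists.

    An identifier present in both layers with conflicting directions is
    retained once and flagged; its direction follows the larger absolute
    log-ratio when both magnitudes are known, otherwise the transcript
    layer's call.
    """
    if transcripts.condition != proteins.condition:
        raise ValueError(
            f"condition mismatch: {transcripts.condition!r} vs {proteins.condition!r}"
        )
    by_id = {e.identifier: e for e in transcripts.entries}
    merged: dict[str, DeregEntry] = dict(by_id)
    for e in proteins.entries:
        prev = merged.get(e.identifier)
        if prev is None:
            merged[e.identifier] = e
        elif prev.direction != e.direction:
            if (prev.magnitude is not None and e.magnitude is not None
                    and abs(e.magnitude) > abs(prev.magnitude)):
                keep = e
            else:
                keep = prev
            merged[e.identifier] = DeregEntry(
                keep.identifier, keep.direction, keep.magnitude, conflict=True
            )
    return DeregulationList(transcripts.condition, "merged",
                            tuple(merged.values()))


def classify_overlap(a: DeregulationList, b: DeregulationList) -> OverlapResult:
    """Partition the shared identifiers of two lists by sign agreement."""
    da, db = a.directions, b.directions
    common = set(da) & set(db)
    up = frozenset(i for i in common if da[i] == 1 and db[i] == 1)
    down = frozenset(i for i in common if da[i] == -1 and db[i] == -1)
    contra = frozenset(i for i in common if da[i] != db[i])
    return OverlapResult(
        common_ids=frozenset(common),
        n_up_both=len(up), n_down_both=len(down), n_contra=len(contra),
        n_unique_a=len(da) - len(common), n_unique_b=len(db) - len(common),
        up_both=up, down_both=down, contra=contra,
    )


def fisher_enrichment(query: DeregulationList | Iterable[str],
                      sets: Sequence[GeneSet],
                      universe: Iterable[str]) -> list[EnrichmentRow]:
    """One-sided over-representation of each gene set in the query list.

    For a universe of M identifiers containing n members of the set, and a
    query of N identifiers with k hits, the p-value is the upper
    hypergeometric tail P(X >= k).  Benjamini-Hochberg q-values are
    computed across all tested sets; rows are returned sorted by p-value
    (ties broken by set name for determinism).
    """
    universe_set = frozenset(u.strip().upper() for u in universe)
    if not universe_set:
        raise ValueError("universe is empty")
    if isinstance(query, DeregulationList):
        query_ids = query.identifiers
    else:
        query_ids = frozenset(q.strip().upper() for q in query)
    stray = query_ids - universe_set
    if stray:
        raise ValueError(
            f"query identifiers missing from the universe: {sorted(stray)}"
        )

    M, N = len(universe_set), len(query_ids)
    rows = []
    for gs in sets:
        members = gs.members & universe_set
        hit_ids = frozenset(members & query_ids)
        k, n = len(hit_ids), len(members)
        # upper tail P(X >= k); sf is P(X > k-1)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((gs.name, n, k, hit_ids, min(p, 1.0)))

    qvals = bh_fdr([r[4] for r in rows]) if rows else []
    out = [
        EnrichmentRow(name, n, k, hit_ids, p, q)
        for (name, n, k, hit_ids, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    import numpy as np

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def compare_enrichment(rows_a: Sequence[EnrichmentRow],
                       rows_b: Sequence[EnrichmentRow],
                       fdr_cut: float = 0.05) -> dict[str, frozenset[str]]:
    """Shared vs condition-unique gene sets passing an FDR threshold.

    Both inputs must have been computed against the same gene-set
    collection (identical set names).
    """
    names_a = {r.set_name for r in rows_a}
    names_b = {r.set_name for r in rows_b}
    if names_a != names_b:
        raise ValueError("enrichment results cover different gene-set collections")
    pass_a = {r.set_name for r in rows_a if r.fdr <= fdr_cut}
    pass_b = {r.set_name for r in rows_b if r.fdr <= fdr_cut}
    return {
        "shared": frozenset(pass_a & pass_b),
        "unique_a": frozenset(pass_a - pass_b),
        "unique_b": frozenset(pass_b - pass_a),
    }
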