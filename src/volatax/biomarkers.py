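"""Essential / semi-essential biomarker classification and the dichotomous key.

Significant compound vectors are split by squared length: essential
biomarkers (EB, inner circle) at >= 0.49 and semi-essential biomarkers
(SEB, outer circle) in [0.29, 0.49); shorter vectors are dropped. Each
vector is attributed to the a-priori group whose centroid it points
toward. Taxon entries accumulate across rounds into a dichotomous key,
against which unknown presence profiles are matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import KeyConstructionError
from .cap import CAPResult, CompoundVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiomarkerThresholds:
    """Vector-length thresholds for EB/SEB classification.

    ``sig_cutoff``/``sig_mode`` define per-round significance; vectors with
    squared length >= ``eb_low`` are EBs, those in [``seb_low``, ``eb_low``)
    SEBs. Lengths above ``eb_high`` are still EBs, only logged.
    """

    eb_low: float = 0.49
    eb_high: float = 0.97
    seb_low: float = 0.29
    sig_cutoff: float = 0.3
    sig_mode: str = "len2"

    def __post_init__(self):
        if not (0 <= self.seb_low < self.eb_low <= self.eb_high <= 2):
            raise ValueError(
                "thresholds must satisfy 0 <= seb_low < eb_low <= eb_high <= 2"
            )
        if self.sig_mode not in ("len2", "abs_r"):
            raise ValueError(f"unknown sig_mode {self.sig_mode!r}")


@dataclass(frozen=True)
class BiomarkerSet:
    """EB/SEB compounds attributed to one group in one round."""

    group_label: str
    eb: tuple[tuple[str, float], ...]   # (compound_id, squared_length)
    seb: tuple[tuple[str, float], ...]
    round_id: str

    def __post_init__(self):
        overlap = {c for c, _ in self.eb} & {c for c, _ in self.seb}
        if overlap:
            raise KeyConstructionError(
                f"compounds {sorted(overlap)} classified both EB and SEB "
                f"for {self.group_label!r}"
            )


@dataclass(frozen=True)
class KeyTaxon:
    taxon: str
    eb: tuple[tuple[str, float], ...]
    seb: tuple[tuple[str, float], ...]
    provenance: tuple[str, ...]

    @property
    def eb_compounds(self) -> frozenset:
        return frozenset(c for c, _ in self.eb)

    @property
    def seb_compounds(self) -> frozenset:
        return frozenset(c for c, _ in self.seb)


@dataclass(frozen=True)
class DichotomousKey:
    """Per-taxon EB (inner circle) and SEB (outer circle) sets."""

    taxa: tuple[KeyTaxon, ...]

    def __post_init__(self):
        labels = [t.taxon for t in self.taxa]
        if len(set(labels)) != len(labels):
            raise KeyConstructionError("duplicate taxon labels in key")
        for t in self.taxa:
            if not t.eb:
                raise KeyConstructionError(
                    f"taxon {t.taxon!r} has no essential biomarker"
                )

    @property
    def taxon_labels(self) -> tuple[str, ...]:
        return tuple(t.taxon for t in self.taxa)

    def taxon(self, label: str) -> KeyTaxon:
        for t in self.taxa:
            if t.taxon == label:
                return t
        raise KeyError(label)

    def vocabulary(self) -> frozenset:
        vocab: set = set()
        for t in self.taxa:
            vocab |= t.eb_compounds | t.seb_compounds
        return frozenset(vocab)


@dataclass(frozen=True)
class Identification:
    """Ranked match of a presence profile against a dichotomous key."""

    status: str                       # identified | ambiguous | unidentified
    candidates: tuple[dict, ...]      # sorted by score descending

    def top(self) -> dict | None:
        return self.candidates[0] if self.candidates else None


# ---------------------------------------------------------------------------
# Vector -> group attribution and EB/SEB classification
# ---------------------------------------------------------------------------

def assign_vectors_to_groups(
    vectors: Sequence[CompoundVector], cap: CAPResult
) -> dict[str, str]:
    """Attribute each significant vector to the group it points toward.

    The chosen group maximizes the projection of its centroid (first two
    canonical axes) onto the vector's (X, Y); vectors with no positive
    projection stay unassigned.
    """
    axes = min(2, cap.group_centroids.shape[1])
    centroids = cap.group_centroids[:, :axes]
    assignment: dict[str, str] = {}
    for vec in vectors:
        if not vec.significant:
            continue
        direction = np.array([vec.x, vec.y][:axes])
        proj = centroids @ direction
        best = int(np.argmax(proj))
        if proj[best] > 0:
            assignment[vec.compound_id] = cap.group_order[best]
    return assignment


def classify_biomarkers(
    vectors: Sequence[CompoundVector],
    thresholds: BiomarkerThresholds,
    assignment: Mapping[str, str],
    round_id: str = "",
) -> dict[str, BiomarkerSet]:
    """Partition significant vectors into per-group EB/SEB sets.

    squared length >= eb_low -> EB; [seb_low, eb_low) -> SEB; below ->
    dropped. Values above eb_high remain EBs (logged): the upper bound is
    an empirical maximum, not an exclusion.
    """
    eb: dict[str, list] = {}
    seb: dict[str, list] = {}
    for vec in vectors:
        if not vec.significant:
            continue
        group = assignment.get(vec.compound_id)
        if group is None:
            continue
        length = vec.squared_length
        if length >= thresholds.eb_low:
            if length > thresholds.eb_high:
                logger.info(
                    "compound %r squared length %.3f exceeds eb_high=%.2f; "
                    "kept as EB", vec.compound_id, length, thresholds.eb_high,
                )
            eb.setdefault(group, []).append((vec.compound_id, length))
        elif length >= thresholds.seb_low:
            seb.setdefault(group, []).append((vec.compound_id, length))
    out = {}
    for group in sorted(set(eb) | set(seb)):
        out[group] = BiomarkerSet(
            group_label=group,
            eb=tuple(sorted(eb.get(group, ()))),
            seb=tuple(sorted(seb.get(group, ()))),
            round_id=round_id,
        )
    return out


# ---------------------------------------------------------------------------
# Key construction and profile matching
# ---------------------------------------------------------------------------

def build_key(round_sets: Iterable[BiomarkerSet]) -> DichotomousKey:
    """Union per-taxon EB/SEB sets over rounds into a dichotomous key.

    A compound that is EB in one round and SEB in another for the same
    taxon counts as EB. A taxon with no EB is a construction error.
    """
    eb: dict[str, dict[str, float]] = {}
    seb: dict[str, dict[str, float]] = {}
    provenance: dict[str, list[str]] = {}
    order: list[str] = []
    for bset in round_sets:
        taxon = bset.group_label
        if taxon not in order:
            order.append(taxon)
            eb[taxon], seb[taxon], provenance[taxon] = {}, {}, []
        if bset.round_id and bset.round_id not in provenance[taxon]:
            provenance[taxon].append(bset.round_id)
        for compound, length in bset.eb:
            eb[taxon][compound] = max(length, eb[taxon].get(compound, 0.0))
        for compound, length in bset.seb:
            seb[taxon][compound] = max(length, seb[taxon].get(compound, 0.0))
    taxa = []
    missing = [t for t in order if not eb[t]]
    if missing:
        raise KeyConstructionError(
            f"taxa without any essential biomarker: {missing}"
        )
    for taxon in order:
        seb_clean = {c: l for c, l in seb[taxon].items() if c not in eb[taxon]}
        taxa.append(
            KeyTaxon(
                taxon=taxon,
                eb=tuple(sorted(eb[taxon].items())),
                seb=tuple(sorted(seb_clean.items())),
                provenance=tuple(provenance[taxon]),
            )
        )
    return DichotomousKey(taxa=tuple(taxa))


def match_profile(
    profile: Iterable[str],
    key: DichotomousKey,
    eb_accept: float = 1.0,
    margin: float = 0.25,
) -> Identification:
    """Match a presence profile (set of detected compounds) against a key.

    Per taxon: eb_match_fraction = |EB ∩ profile| / |EB| (seb likewise);
    score = eb_match_fraction + 0.5 * seb_match_fraction. Identified iff
    the top candidate reaches ``eb_accept`` on its EBs and beats the
    runner-up by ``margin``; unidentified iff no taxon reaches
    ``eb_accept``; otherwise ambiguous.
    """
    detected = set(profile)
    unknown = detected - set(key.vocabulary())
    if unknown:
        logger.warning(
            "%d profile compound(s) outside the key vocabulary ignored",
            len(unknown),
        )
    candidates = []
    for t in key.taxa:
        eb_frac = len(t.eb_compounds & detected) / len(t.eb_compounds)
        seb_frac = (
            len(t.seb_compounds & detected) / len(t.seb_compounds)
            if t.seb_compounds else 0.0
        )
        candidates.append(
            {
                "taxon": t.taxon,
                "eb_match_fraction": eb_frac,
                "seb_match_fraction": seb_frac,
                "score": eb_frac + 0.5 * seb_frac,
            }
        )
    candidates.sort(key=lambda c: (-c["score"], c["taxon"]))
    if not candidates or candidates[0]["eb_match_fraction"] < eb_accept:
        status = "unidentified"
    elif (
        len(candidates) == 1
        or candidates[0]["score"] - candidates[1]["score"] >= margin
    ):
        status = "identified"
    else:
        status = "ambiguous"
    return Identification(status=status, candidates=tuple(candidates))
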