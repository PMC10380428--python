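"""Hierarchical rounds of CAP: run, peel off separated groups, repeat.

The cascade is plan-driven: each round names its a-priori groups (at least
three, optionally including an outgroup added only to satisfy that
minimum), the preprocessing parameters, the significance and EB/SEB
thresholds, and which groups to remove from the sample pool afterwards.
Biomarker sets of removed groups — and, in the final round, of all
remaining non-outgroup groups — feed the dichotomous key; outgroup
biomarkers never enter the key.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import CascadeError, ConfigurationError, VocabularyError
from .io_formats import PeakTable, SampleTable
from . import preprocess as pp
from . import cap as cap_mod
from .cap import CAPResult, CompoundVector, cap_analysis, compound_vectors
from .biomarkers import (
    BiomarkerSet,
    BiomarkerThresholds,
    DichotomousKey,
    Identification,
    assign_vectors_to_groups,
    build_key,
    classify_biomarkers,
    match_profile,
)

logger = logging.getLogger(__name__)

PLAN_SCHEMA_VERSION = 1

THREE_GROUP_RULE = (
    "a CAP round requires at least three a-priori groups "
    "(add an outgroup to reach the minimum)"
)


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoundPlan:
    round_id: str
    groups: tuple[str, ...]
    grouping_variable: str = "group_label"     # group_label | host_plant
    outgroup: str | None = None                # must be listed in groups
    transform: str | None = None               # None -> cascade default
    metric: str | None = None
    presence_threshold: float | None = None
    thresholds: BiomarkerThresholds = field(default_factory=BiomarkerThresholds)
    m: int | None = None                       # None -> select by LOO scan
    n_perm: int | None = None
    seed: int | None = None
    groups_to_remove_after: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(
            self, "groups_to_remove_after", tuple(self.groups_to_remove_after)
        )
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError(
                f"round {self.round_id!r}: duplicate groups"
            )
        if len(self.groups) < 3:
            raise ConfigurationError(
                f"round {self.round_id!r}: {len(self.groups)} groups given; "
                + THREE_GROUP_RULE
            )
        if self.outgroup is not None and self.outgroup not in self.groups:
            raise ConfigurationError(
                f"round {self.round_id!r}: outgroup {self.outgroup!r} not in groups"
            )
        extra = set(self.groups_to_remove_after) - set(self.groups)
        if extra:
            raise ConfigurationError(
                f"round {self.round_id!r}: groups_to_remove_after not in "
                f"groups: {sorted(extra)}"
            )


@dataclass(frozen=True)
class CascadePlan:
    rounds: tuple[RoundPlan, ...]
    transform: str = "relative"
    metric: str = "bray-curtis"
    presence_threshold: float = 0.0
    n_perm: int = 99
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "rounds", tuple(self.rounds))
        if not self.rounds:
            raise ConfigurationError("cascade plan needs at least one round")
        ids = [r.round_id for r in self.rounds]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate round ids: {ids}")

    # -- JSON ---------------------------------------------------------------
    @classmethod
    def from_dict(cls, payload: Mapping) -> "CascadePlan":
        defaults = payload.get("defaults", {})
        rounds = []
        for entry in payload["rounds"]:
            thr = BiomarkerThresholds(**entry.get("thresholds", {}))
            rounds.append(
                RoundPlan(
                    round_id=str(entry["round_id"]),
                    groups=tuple(entry["groups"]),
                    grouping_variable=entry.get("grouping_variable", "group_label"),
                    outgroup=entry.get("outgroup"),
                    transform=entry.get("transform"),
                    metric=entry.get("metric"),
                    presence_threshold=entry.get("presence_threshold"),
                    thresholds=thr,
                    m=entry.get("m"),
                    n_perm=entry.get("n_perm"),
                    seed=entry.get("seed"),
                    groups_to_remove_after=tuple(
                        entry.get("groups_to_remove_after", ())
                    ),
                )
            )
        return cls(
            rounds=tuple(rounds),
            transform=defaults.get("transform", "relative"),
            metric=defaults.get("metric", "bray-curtis"),
            presence_threshold=defaults.get("presence_threshold", 0.0),
            n_perm=defaults.get("n_perm", 99),
            seed=defaults.get("seed", 0),
        )

    @classmethod
    def from_file(cls, path) -> "CascadePlan":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "schema_version": PLAN_SCHEMA_VERSION,
            "defaults": {
                "transform": self.transform,
                "metric": self.metric,
                "presence_threshold": self.presence_threshold,
                "n_perm": self.n_perm,
                "seed": self.seed,
            },
            "rounds": [
                {
                    "round_id": r.round_id,
                    "groups": list(r.groups),
                    "grouping_variable": r.grouping_variable,
                    "outgroup": r.outgroup,
                    "transform": r.transform,
                    "metric": r.metric,
                    "presence_threshold": r.presence_threshold,
                    "thresholds": asdict(r.thresholds),
                    "m": r.m,
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                    "groups_to_remove_after": list(r.groups_to_remove_after),
                }
                for r in self.rounds
            ],
        }

    def to_file(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# Round execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoundResult:
    round_id: str
    cap: CAPResult
    vectors: tuple[CompoundVector, ...]
    biomarker_sets: dict[str, BiomarkerSet]
    compound_ids: tuple[str, ...]          # compounds analysed in this round
    sample_ids: tuple[str, ...]            # averaged samples analysed
    group_of_sample: dict[str, str]

    def report_dict(self) -> dict:
        cap = self.cap
        return {
            "round_id": self.round_id,
            "m": cap.m,
            "delta_sq": [float(x) for x in cap.delta_sq],
            "trace": cap.trace_statistic,
            "loo_error_pct": cap.loo_error_pct,
            "confusion": {
                "groups": list(cap.confusion.index),
                "counts": cap.confusion.to_numpy().tolist(),
            } if cap.confusion is not None else None,
            "p_trace": cap.p_trace,
            "p_first": cap.p_first,
            "vectors": [
                {
                    "compound_id": v.compound_id,
                    "x": round(v.x, 12),
                    "y": round(v.y, 12),
                    "len2": round(v.squared_length, 12),
                    "significant": bool(v.significant),
                }
                for v in self.vectors
            ],
            "biomarkers": {
                g: {
                    "eb": [[c, round(l, 12)] for c, l in b.eb],
                    "seb": [[c, round(l, 12)] for c, l in b.seb],
                }
                for g, b in sorted(self.biomarker_sets.items())
            },
        }


@dataclass(frozen=True)
class CascadeResult:
    rounds: tuple[RoundResult, ...]
    key: DichotomousKey


def _resolve(value, default):
    return default if value is None else value


def run_round(
    pt: PeakTable,
    st: SampleTable,
    plan: RoundPlan,
    defaults: CascadePlan | None = None,
) -> RoundResult:
    """Execute one CAP round: preprocess, ordinate, classify biomarkers."""
    defaults = defaults or CascadePlan(rounds=(plan,))
    transform = _resolve(plan.transform, defaults.transform)
    metric = _resolve(plan.metric, defaults.metric)
    threshold = _resolve(plan.presence_threshold, defaults.presence_threshold)
    n_perm = _resolve(plan.n_perm, defaults.n_perm)
    seed = _resolve(plan.seed, defaults.seed)

    group_of = st.group_of_sample(plan.grouping_variable)
    present = {g for s, g in group_of.items() if s in pt.sample_ids}
    missing = set(plan.groups) - present
    if missing:
        raise CascadeError(
            f"round {plan.round_id!r}: groups absent from data: "
            f"{sorted(missing)}"
        )
    samples = [s for s in pt.sample_ids if group_of.get(s) in set(plan.groups)]
    sub_pt = pt.subset_samples(samples)
    sub_st = st.subset(samples)

    try:
        averaged = pp.average_technical_replicates(sub_pt, sub_st)
        rep_group = {}
        rep_of = sub_st.replicate_group_of_sample()
        for s in samples:
            rep_group[rep_of[s]] = group_of[s]
        averaged = pp.prune_compounds(averaged)
        transformed = pp.transform_abundances(
            averaged, transform, detection_threshold=threshold
        )
        dm = pp.compute_distance_matrix(transformed, metric)
        groups = [rep_group[s] for s in dm.sample_ids]
        cap = cap_analysis(
            dm, groups, m=plan.m, n_perm=n_perm, seed=seed
        )
        vectors = compound_vectors(
            transformed, cap,
            sig_cutoff=plan.thresholds.sig_cutoff,
            sig_mode=plan.thresholds.sig_mode,
        )
        assignment = assign_vectors_to_groups(vectors, cap)
        sets = classify_biomarkers(
            vectors, plan.thresholds, assignment, round_id=plan.round_id
        )
    except Exception as exc:
        if isinstance(exc, CascadeError):
            raise
        raise CascadeError(f"round {plan.round_id!r}: {exc}") from exc
    return RoundResult(
        round_id=plan.round_id,
        cap=cap,
        vectors=tuple(vectors),
        biomarker_sets=sets,
        compound_ids=transformed.compound_ids,
        sample_ids=transformed.sample_ids,
        group_of_sample=dict(zip(dm.sample_ids, groups)),
    )


def run_cascade(
    pt: PeakTable, st: SampleTable, plan: CascadePlan
) -> CascadeResult:
    """Run all rounds, peeling off removed groups, and build the key."""
    current_pt = pt
    current_st = st
    results: list[RoundResult] = []
    key_sets: list[BiomarkerSet] = []
    for i, rp in enumerate(plan.rounds):
        group_of = current_st.group_of_sample(rp.grouping_variable)
        available = {group_of[s] for s in current_pt.sample_ids}
        if len(available & set(rp.groups)) < 3:
            raise CascadeError(
                f"round {rp.round_id!r}: fewer than 3 of its groups remain "
                f"in the sample pool; " + THREE_GROUP_RULE
            )
        result = run_round(current_pt, current_st, rp, defaults=plan)
        results.append(result)
        terminal = set(rp.groups_to_remove_after)
        if i == len(plan.rounds) - 1:
            terminal |= set(rp.groups)
        if rp.outgroup is not None:
            terminal.discard(rp.outgroup)
        outgroups = current_st.outgroup_labels()
        for g in sorted(terminal - outgroups):
            bset = result.biomarker_sets.get(g)
            if bset is not None:
                key_sets.append(bset)
            else:
                logger.warning(
                    "round %s: terminal group %r yielded no biomarkers",
                    rp.round_id, g,
                )
        if rp.groups_to_remove_after:
            keep = [
                s for s in current_pt.sample_ids
                if group_of[s] not in set(rp.groups_to_remove_after)
            ]
            if keep:
                current_pt = pp.prune_compounds(current_pt.subset_samples(keep))
                current_st = current_st.subset(keep)
    return CascadeResult(rounds=tuple(results), key=build_key(key_sets))


def suggest_removals(result: RoundResult) -> list[str]:
    """Groups with zero LOO misallocations and centroid silhouette > 0.5.

    Advisory only — the plan decides what is actually removed.
    """
    cap = result.cap
    if cap.confusion is None:
        return []
    suggestions = []
    centroids = cap.group_centroids
    for i, g in enumerate(cap.group_order):
        row = cap.confusion.loc[g]
        clean = row.drop(g).sum() == 0 and cap.confusion[g].drop(g).sum() == 0
        others = np.delete(centroids, i, axis=0)
        if others.size == 0:
            continue
        sep = np.linalg.norm(others - centroids[i], axis=1).min()
        scores = cap.canonical_scores[
            np.array([x == g for x in cap.groups])
        ]
        spread = np.linalg.norm(
            scores - centroids[i], axis=1
        ).mean() if len(scores) else 0.0
        silhouette = (sep - spread) / max(sep, spread) if max(sep, spread) else 0.0
        if clean and silhouette > 0.5:
            suggestions.append(g)
    return suggestions


# ---------------------------------------------------------------------------
# Unknown identification
# ---------------------------------------------------------------------------

def presence_profile(
    pt: PeakTable,
    st: SampleTable | None = None,
    detection_threshold: float = 0.0,
) -> set[str]:
    """Replicate-averaged presence set of a (possibly replicated) profile."""
    if st is not None:
        pt = pp.average_technical_replicates(pt, st)
    else:
        pt = pp.average_technical_replicates(
            pt,
            SampleTable(
                _single_group_frame(pt.sample_ids)
            ),
        )
    detected = (pt.abundances > detection_threshold).any(axis=1)
    return {c for c, d in zip(pt.compound_ids, detected) if d}


def _single_group_frame(sample_ids):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "replicate_group": ["unknown"] * len(sample_ids),
            "group_label": ["unknown"] * len(sample_ids),
        }
    )


def identify_unknown(
    unknown_pt: PeakTable,
    key: DichotomousKey,
    unknown_st: SampleTable | None = None,
    detection_threshold: float = 0.0,
    eb_accept: float = 1.0,
    margin: float = 0.25,
) -> Identification:
    """Match an unknown profile against a dichotomous key (key mode)."""
    if not set(unknown_pt.compound_ids) & set(key.vocabulary()):
        raise VocabularyError(
            "unknown profile measures no compounds from the key vocabulary"
        )
    profile = presence_profile(unknown_pt, unknown_st, detection_threshold)
    return match_profile(profile, key, eb_accept=eb_accept, margin=margin)


@dataclass(frozen=True)
class UnknownCAPReport:
    """CAP-mode diagnosis: the unknown appended as its own a-priori group."""

    round_result: RoundResult
    separated: bool                    # unknown samples all allocated to "unknown"
    unknown_biomarkers: BiomarkerSet | None


def identify_unknown_cap(
    unknown_pt: PeakTable,
    pt: PeakTable,
    st: SampleTable,
    plan: RoundPlan | None = None,
    defaults: CascadePlan | None = None,
    unknown_label: str = "unknown",
) -> UnknownCAPReport:
    """Run one CAP round with the unknown included as its own group."""
    shared = [c for c in pt.compound_ids if c in set(unknown_pt.compound_ids)]
    if not shared:
        raise VocabularyError(
            "unknown profile shares no compounds with the reference table"
        )
    merged_compounds = list(pt.compound_ids) + [
        c for c in unknown_pt.compound_ids if c not in set(pt.compound_ids)
    ]
    n_ref, n_unk = pt.n_samples, unknown_pt.n_samples
    matrix = np.zeros((len(merged_compounds), n_ref + n_unk))
    ref_index = {c: i for i, c in enumerate(merged_compounds)}
    for i, c in enumerate(pt.compound_ids):
        matrix[ref_index[c], :n_ref] = pt.abundances[i]
    for i, c in enumerate(unknown_pt.compound_ids):
        matrix[ref_index[c], n_ref:] = unknown_pt.abundances[i]
    unk_ids = [
        s if s not in set(pt.sample_ids) else f"unknown:{s}"
        for s in unknown_pt.sample_ids
    ]
    merged_pt = PeakTable(
        compound_ids=tuple(merged_compounds),
        sample_ids=tuple(pt.sample_ids) + tuple(unk_ids),
        abundances=matrix,
    )
    import pandas as pd

    # one replicate group per unknown column so the unknown contributes
    # several samples to its a-priori group and LOO is defined for it
    unk_meta = pd.DataFrame(
        {
            "sample_id": unk_ids,
            "replicate_group": unk_ids,
            "group_label": [unknown_label] * n_unk,
        }
    )
    merged_st = SampleTable(
        pd.concat([st.table, SampleTable(unk_meta).table], ignore_index=True)
    )
    group_of = merged_st.group_of_sample()
    ref_groups = sorted({group_of[s] for s in pt.sample_ids})
    if plan is None:
        plan = RoundPlan(
            round_id="unknown-cap",
            groups=tuple(ref_groups) + (unknown_label,),
        )
    result = run_round(merged_pt, merged_st, plan, defaults=defaults)
    confusion = result.cap.confusion
    separated = bool(
        confusion is not None
        and unknown_label in confusion.index
        and confusion.loc[unknown_label, unknown_label]
        == confusion.loc[unknown_label].sum()
        and confusion[unknown_label].sum()
        == confusion.loc[unknown_label, unknown_label]
    )
    return UnknownCAPReport(
        round_result=result,
        separated=separated,
        unknown_biomarkers=result.biomarker_sets.get(unknown_label),
    )
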