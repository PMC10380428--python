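"""Synthetic multi-species volatile datasets with planted ground truth.

Emulates the statistical structure the pipeline assumes: species-specific
always-present marker compounds (planted EBs), probabilistic semi-specific
markers (planted SEBs), one widely shared high-abundance compound absent
from a configurable subset of species (the alarm-pheromone analogue),
optional host-plant-linked compounds, technical replicates with log-normal
multiplicative noise, and per-role detection dropout.

Planted EBs are disjoint across species by construction; SEB presence is
drawn per biological sample, so set ``p_seb`` to 0 or 1 to obtain the exact
noise-free limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SyntheticSpecError
from .io_formats import PeakTable, SampleTable
from . import preprocess as pp
from .biomarkers import BiomarkerThresholds
from .cascade import CascadePlan, CascadeResult, RoundPlan, run_cascade

logger = logging.getLogger(__name__)

DEFAULT_MEDIANS = {
    "eb": 100.0,        # species marker, ~100x background
    "seb": 20.0,
    "shared": 300.0,    # shared marker dominates profiles that carry it
    "host": 50.0,
    "background": 1.0,
}
DEFAULT_DROPOUT = {
    "eb": 0.05,
    "seb": 0.05,
    "shared": 0.02,
    "host": 0.05,
    "background": 0.10,
}
ROLE_CLASS = {
    "eb": "alkane",
    "seb": "terpene",
    "shared": "sesquiterpene",
    "host": "monoterpene",
    "background": "ester",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a multi-species volatile dataset."""

    n_species: int = 10
    n_compounds: int = 81
    n_eb: int = 2                      # planted EBs per species
    n_seb: int = 2                     # planted SEBs per species
    p_seb: float = 0.25                # SEB presence prob per biological sample
    n_shared_species: int = 8          # first k species carry the shared marker
    host_plants: Mapping[str, Sequence[str]] | None = None
    n_biological: int = 6
    n_replicates: int = 3
    background_presence: float = 1.0   # per (species, compound); <1 plants gaps
    sigma: float = 0.3                 # log-normal noise scale
    medians: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEDIANS))
    dropout: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.n_compounds, self.n_biological,
               self.n_replicates) < 1 or self.n_eb < 1 or self.n_seb < 0:
            raise SyntheticSpecError("counts must be positive")
        for p in (self.p_seb, self.background_presence,
                  *self.dropout.values()):
            if not 0.0 <= p <= 1.0:
                raise SyntheticSpecError(f"probability {p} outside [0, 1]")
        if not 0 <= self.n_shared_species <= self.n_species:
            raise SyntheticSpecError("n_shared_species outside [0, n_species]")
        planted = self.n_species * (self.n_eb + self.n_seb) + 1 + self._n_host()
        if planted > self.n_compounds:
            raise SyntheticSpecError(
                f"{planted} planted markers exceed n_compounds={self.n_compounds}"
            )

    def _n_host(self) -> int:
        if not self.host_plants:
            return 0
        plants = set()
        for hosts in self.host_plants.values():
            plants.update(hosts)
        return len(plants)

    @property
    def species(self) -> tuple[str, ...]:
        width = len(str(self.n_species))
        return tuple(f"sp{i + 1:0{width}d}" for i in range(self.n_species))

    @property
    def shared_species(self) -> tuple[str, ...]:
        return self.species[: self.n_shared_species]

    @property
    def lacking_species(self) -> tuple[str, ...]:
        return self.species[self.n_shared_species:]

    def to_dict(self) -> dict:
        out = asdict(self)
        out["medians"] = dict(self.medians)
        out["dropout"] = dict(self.dropout)
        if self.host_plants is not None:
            out["host_plants"] = {k: list(v) for k, v in self.host_plants.items()}
        return out

    @classmethod
    def from_file(cls, path) -> "SyntheticSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruth:
    """Planted marker sets backing recovery experiments."""

    species_eb: dict[str, tuple[str, ...]]
    species_seb: dict[str, tuple[str, ...]]
    shared_marker: str
    shared_species: tuple[str, ...]
    host_compounds: dict[str, str]     # plant -> compound

    def to_dict(self) -> dict:
        return {
            "species_eb": {k: list(v) for k, v in self.species_eb.items()},
            "species_seb": {k: list(v) for k, v in self.species_seb.items()},
            "shared_marker": self.shared_marker,
            "shared_species": list(self.shared_species),
            "host_compounds": dict(self.host_compounds),
        }


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[PeakTable, SampleTable, GroundTruth]:
    """Draw a reproducible dataset; see module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    species = spec.species
    width = len(str(spec.n_compounds))
    compound_ids = [f"c{i + 1:0{width}d}" for i in range(spec.n_compounds)]

    # role layout: EB blocks, SEB blocks, shared, host, background
    roles: list[tuple[str, object]] = []
    for sp in species:
        roles += [("eb", sp)] * spec.n_eb
    for sp in species:
        roles += [("seb", sp)] * spec.n_seb
    roles.append(("shared", None))
    plants: list[str] = []
    if spec.host_plants:
        for hosts in spec.host_plants.values():
            for h in hosts:
                if h not in plants:
                    plants.append(h)
    roles += [("host", p) for p in plants]
    roles += [("background", None)] * (spec.n_compounds - len(roles))

    species_eb: dict[str, list[str]] = {sp: [] for sp in species}
    species_seb: dict[str, list[str]] = {sp: [] for sp in species}
    host_compound: dict[str, str] = {}
    shared_marker = ""
    for cid, (role, owner) in zip(compound_ids, roles):
        if role == "eb":
            species_eb[owner].append(cid)
        elif role == "seb":
            species_seb[owner].append(cid)
        elif role == "shared":
            shared_marker = cid
        elif role == "host":
            host_compound[owner] = cid

    shared_set = set(spec.shared_species)
    host_of_bio: dict[tuple[str, int], str | None] = {}
    for sp in species:
        hosts = list(spec.host_plants.get(sp, [])) if spec.host_plants else []
        for b in range(spec.n_biological):
            host_of_bio[(sp, b)] = hosts[b % len(hosts)] if hosts else None

    # species-level background presence, biological-level SEB presence
    bg_present = {
        (sp, cid): rng.random() < spec.background_presence
        for sp in species
        for cid, (role, _) in zip(compound_ids, roles)
        if role == "background"
    }
    seb_present = {
        (sp, b, cid): rng.random() < spec.p_seb
        for sp in species
        for b in range(spec.n_biological)
        for cid in species_seb[sp]
    }

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    columns: list[np.ndarray] = []
    for sp in species:
        for b in range(spec.n_biological):
            base = np.zeros(spec.n_compounds)
            role_of = np.empty(spec.n_compounds, dtype=object)
            for i, (cid, (role, owner)) in enumerate(zip(compound_ids, roles)):
                role_of[i] = role
                if role == "eb":
                    present = owner == sp
                elif role == "seb":
                    present = owner == sp and seb_present[(sp, b, cid)]
                elif role == "shared":
                    present = sp in shared_set
                elif role == "host":
                    present = host_of_bio[(sp, b)] == owner
                else:
                    present = bg_present[(sp, cid)]
                if present:
                    base[i] = spec.medians[role] * np.exp(
                        spec.sigma * rng.standard_normal()
                    )
            for r in range(spec.n_replicates):
                noise = np.exp(spec.sigma * rng.standard_normal(spec.n_compounds))
                value = base * noise
                drop_p = np.array([spec.dropout[x] for x in role_of])
                value[rng.random(spec.n_compounds) < drop_p] = 0.0
                sid = f"{sp}_b{b + 1}_r{r + 1}"
                sample_ids.append(sid)
                columns.append(value)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "replicate_group": f"{sp}_b{b + 1}",
                        "group_label": sp,
                        "is_outgroup": False,
                        "host_plant": host_of_bio[(sp, b)],
                        "location": None,
                    }
                )

    annotations = pd.DataFrame(
        {"class": [ROLE_CLASS[role] for role, _ in roles]},
        index=pd.Index(compound_ids, name="compound_id"),
    )
    pt = PeakTable(
        compound_ids=tuple(compound_ids),
        sample_ids=tuple(sample_ids),
        abundances=np.column_stack(columns),
        annotations=annotations,
    )
    st = SampleTable(pd.DataFrame(meta_rows))
    gt = GroundTruth(
        species_eb={sp: tuple(v) for sp, v in species_eb.items()},
        species_seb={sp: tuple(v) for sp, v in species_seb.items()},
        shared_marker=shared_marker,
        shared_species=spec.shared_species,
        host_compounds=host_compound,
    )
    return pt, st, gt


# ---------------------------------------------------------------------------
# Default cascade plan over a synthetic dataset
# ---------------------------------------------------------------------------

def default_cascade_plan(
    spec: SyntheticSpec,
    thresholds: BiomarkerThresholds | None = None,
    n_perm: int = 99,
    seed: int = 0,
) -> CascadePlan:
    """Hierarchical plan: a diagnostic first round over all species, then
    three-group rounds that peel species off until three remain.

    Round 1 mirrors the alarm-pheromone split (all species, nothing
    removed); round 2 isolates the shared-marker-lacking species with one
    carrier as outgroup; later rounds window through the carriers.
    """
    thresholds = thresholds or BiomarkerThresholds()
    species = list(spec.species)
    lacking = list(spec.lacking_species)
    carriers = [sp for sp in species if sp not in lacking]
    if len(carriers) < 3:
        # too few carriers for the peel-off design: single terminal round
        if len(species) < 3:
            raise SyntheticSpecError(
                "default plan needs at least 3 species"
            )
        return CascadePlan(
            rounds=(
                RoundPlan(
                    round_id="A1", groups=tuple(species),
                    thresholds=thresholds,
                ),
            ),
            transform="presence",
            metric="bray-curtis",
            n_perm=n_perm,
            seed=seed,
        )
    rounds = [
        RoundPlan(
            round_id="A1",
            groups=tuple(species),
            thresholds=thresholds,
        )
    ]
    idx = 2
    if lacking:
        rounds.append(
            RoundPlan(
                round_id=f"A{idx}",
                groups=tuple(lacking) + (carriers[0],),
                outgroup=carriers[0] if len(lacking) >= 2 else None,
                thresholds=thresholds,
                groups_to_remove_after=tuple(lacking),
            )
        )
        idx += 1
    remaining = list(carriers)
    while len(remaining) > 3:
        take = remaining[:3]
        k = min(3, len(remaining) - 3)
        k = max(k, 1)
        rounds.append(
            RoundPlan(
                round_id=f"A{idx}",
                groups=tuple(take),
                thresholds=thresholds,
                groups_to_remove_after=tuple(remaining[:k]),
            )
        )
        remaining = remaining[k:]
        idx += 1
    rounds.append(
        RoundPlan(
            round_id=f"A{idx}",
            groups=tuple(remaining),
            thresholds=thresholds,
        )
    )
    # presence/absence drives the separation in every round, mirroring the
    # hierarchical design this generator emulates
    return CascadePlan(
        rounds=tuple(rounds),
        transform="presence",
        metric="bray-curtis",
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Recovery experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    precision: float
    per_species_recall: dict[str, float]
    per_species_precision: dict[str, float]
    round_loo: dict[str, float]
    round1_lacking_isolated: bool
    n_seb_recovered: int
    cascade: CascadeResult | None

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "per_species_recall": dict(self.per_species_recall),
            "per_species_precision": dict(self.per_species_precision),
            "round_loo": dict(self.round_loo),
            "round1_lacking_isolated": self.round1_lacking_isolated,
            "n_seb_recovered": self.n_seb_recovered,
        }


def _lacking_isolated(
    pt: PeakTable, st: SampleTable, plan: CascadePlan, lacking: Sequence[str]
) -> bool:
    """Fig-2-style structure: each shared-marker-lacking species forms its
    own tight cluster, far outside the carrier cluster, in the round-1
    distance space (replicate means, round-1 transform and metric)."""
    if not lacking:
        return True
    averaged = pp.average_technical_replicates(pt, st)
    transformed = pp.transform_abundances(averaged, plan.transform)
    dm = pp.compute_distance_matrix(transformed, plan.metric)
    group_of = st.group_of_sample()
    rep_of = st.replicate_group_of_sample()
    rep_group = {rep_of[s]: group_of[s] for s in st.sample_ids}
    labels = np.array([rep_group[s] for s in dm.sample_ids])
    d = dm.values
    carrier_mask = ~np.isin(labels, list(lacking))
    carrier_d = d[np.ix_(carrier_mask, carrier_mask)]
    n_c = carrier_mask.sum()
    mean_carrier = (
        carrier_d.sum() / (n_c * (n_c - 1)) if n_c > 1 else 0.0
    )
    for sp in lacking:
        mask = labels == sp
        within = d[np.ix_(mask, mask)]
        max_within = within.max() if mask.sum() > 1 else 0.0
        to_others = d[np.ix_(mask, ~mask)]
        if to_others.min() <= max_within:
            return False
        to_carriers = d[np.ix_(mask, carrier_mask)]
        if to_carriers.mean() <= mean_carrier:
            return False
    return True


def eb_recovery_experiment(
    spec: SyntheticSpec,
    plan: CascadePlan | None = None,
    shuffle_labels: bool = False,
    shuffle_seed: int = 0,
) -> RecoveryReport:
    """Generate, cascade, and score recovered EBs against the ground truth.

    Recall/precision are micro-averaged over species on the key's EB sets.
    ``shuffle_labels`` permutes species labels at replicate-group level as a
    negative control.
    """
    pt, st, gt = generate_dataset(spec)
    if plan is None:
        plan = default_cascade_plan(spec, seed=spec.seed)
    if shuffle_labels:
        rng = np.random.default_rng(shuffle_seed)
        df = st.table.copy()
        groups = df["replicate_group"].unique()
        label_of = {
            g: df.loc[df["replicate_group"] == g, "group_label"].iloc[0]
            for g in groups
        }
        shuffled = rng.permutation([label_of[g] for g in groups])
        new_label = dict(zip(groups, shuffled))
        df["group_label"] = df["replicate_group"].map(new_label)
        st = SampleTable(df)
    isolated = _lacking_isolated(pt, st, plan, spec.lacking_species)
    try:
        cascade = run_cascade(pt, st, plan)
    except Exception as exc:
        logger.warning("cascade failed under this spec/labels: %s", exc)
        return RecoveryReport(
            recall=0.0, precision=0.0, per_species_recall={},
            per_species_precision={}, round_loo={},
            round1_lacking_isolated=isolated, n_seb_recovered=0, cascade=None,
        )
    recovered = {
        t.taxon: set(t.eb_compounds) for t in cascade.key.taxa
    }
    tp_total = planted_total = recovered_total = 0
    per_recall, per_precision = {}, {}
    for sp in spec.species:
        planted = set(gt.species_eb[sp])
        rec = recovered.get(sp, set())
        tp = len(planted & rec)
        per_recall[sp] = tp / len(planted) if planted else 1.0
        per_precision[sp] = tp / len(rec) if rec else 0.0
        tp_total += tp
        planted_total += len(planted)
        recovered_total += len(rec)
    n_seb = sum(len(t.seb_compounds) for t in cascade.key.taxa)
    return RecoveryReport(
        recall=tp_total / planted_total if planted_total else 1.0,
        precision=tp_total / recovered_total if recovered_total else 0.0,
        per_species_recall=per_recall,
        per_species_precision=per_precision,
        round_loo={
            r.round_id: float(r.cap.loo_error_pct) for r in cascade.rounds
        },
        round1_lacking_isolated=isolated,
        n_seb_recovered=n_seb,
        cascade=cascade,
    )
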