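"""Tri-fold sample-identity resolution.

Three evidence channels are combined per sequenced sample: (1) an
exclusionary pass keeping only registry individuals compatible with the
inferred sex and species; (2) kinship confirmation, where an observed
kinship coefficient to a genotyped relative must resemble the value
expected from the candidate's known pedigree; (3) an archival-records
channel supplying an optional candidate per sample. A sample is assigned
only when the available channels concord; uniqueness across samples is
enforced by singleton propagation plus maximum bipartite matching, and
every failure mode is a flag, never a forced assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .sexing import FEMALE, MALE, UNDETERMINED

FULL_CONCORDANCE = "full-concordance"
PARTIAL = "partial"
CONFLICT = "conflict"
UNRESOLVED = "unresolved"

_SEX_LETTER = {MALE: "M", FEMALE: "F"}


class _LabIdUnknown:
    """Sentinel: the records review invalidated the reported lab id but
    could not supply a replacement (printed as an em-dash in reports)."""

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return "LAB_ID_UNKNOWN"


#: distinct from None (None = records channel silent, reported id stands)
LAB_ID_UNKNOWN = _LabIdUnknown()


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """Reported (possibly wrong) metadata attached to one sequenced sample."""

    biosample: str
    lab_id: str | None
    studbook: str | None
    name: str
    species: str
    sex: str  # "M" / "F"


@dataclass(frozen=True)
class RelativeLink:
    """A genotyped relative of a registry individual, with the
    pedigree-expected kinship coefficient of the pair."""

    relative_id: str
    phi_exp: float
    relationship: str = ""


@dataclass(frozen=True)
class Individual:
    """A candidate source individual as recorded in the registry."""

    name: str
    studbook: str
    sex: str  # "M" / "F"
    species: str
    relatives: tuple[RelativeLink, ...] = ()


class Registry:
    """Candidate individuals keyed by name; studbook numbers unique."""

    def __init__(self, individuals: list[Individual]) -> None:
        self.individuals = {ind.name: ind for ind in individuals}
        if len(self.individuals) != len(individuals):
            raise ValueError("duplicate individual names in registry")
        sbs = [ind.studbook for ind in individuals]
        if len(set(sbs)) != len(sbs):
            raise ValueError("duplicate studbook numbers in registry")

    def __getitem__(self, name: str) -> Individual:
        return self.individuals[name]

    def __contains__(self, name: str) -> bool:
        return name in self.individuals

    def names(self) -> list[str]:
        return sorted(self.individuals)

    def relative_ids(self) -> set[str]:
        return {
            link.relative_id
            for ind in self.individuals.values()
            for link in ind.relatives
        }


@dataclass(frozen=True)
class KinshipHit:
    """An observed kinship signal between a sample and a genotyped relative."""

    relative_id: str
    phi_hat: float
    deltas: tuple[float, float, float] | None = None
    n_snps: int | None = None


@dataclass
class SampleEvidence:
    """Per-sample evidence feeding the resolver."""

    biosample: str
    sex_call: str  # male / female / undetermined
    species_call: str  # population label or "admixed"
    xy_ratio: float | None = None
    kinship_hits: list[KinshipHit] = field(default_factory=list)
    records_candidate: str | None = None
    #: corrected lab id from the records review: None = channel silent
    #: (reported id stands), LAB_ID_UNKNOWN = reported id invalidated,
    #: a string = corrected value
    records_lab_id: object = None


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    biosample: str
    individual: str | None  # assigned name, or None
    lab_id: object  # records-channel lab id (see SampleEvidence.records_lab_id)
    flag: str  # full-concordance / partial / conflict / unresolved
    candidate_set: tuple[str, ...]
    kinship_candidate: str | None
    records_candidate: str | None
    sex_call: str
    species_call: str


@dataclass
class IdentityAssignment:
    assignments: dict[str, Assignment]

    def assigned(self) -> dict[str, str]:
        return {
            b: a.individual
            for b, a in self.assignments.items()
            if a.individual is not None
        }


@dataclass(frozen=True)
class DiscrepancySummary:
    n_relabelled: int
    n_misattributed: int
    n_sex_contradicted: int
    n_unresolved: int


# ---------------------------------------------------------------------------
# channel 1: exclusion by sex and species
# ---------------------------------------------------------------------------

def candidate_sets(
    evidence: list[SampleEvidence], registry: Registry
) -> dict[str, set[str]]:
    """Registry individuals compatible with each sample's inferred sex and
    species. An undetermined sex call matches both sexes; an "admixed"
    species call matches no purebred registry individual (empty set)."""
    out: dict[str, set[str]] = {}
    for ev in evidence:
        if ev.sex_call == UNDETERMINED:
            sex_ok = set(_SEX_LETTER.values())
        else:
            sex_ok = {_SEX_LETTER[ev.sex_call]}
        cands = {
            name
            for name, ind in registry.individuals.items()
            if ind.sex in sex_ok
            and ev.species_call != "admixed"
            and ind.species == ev.species_call
        }
        out[ev.biosample] = cands
    return out


# ---------------------------------------------------------------------------
# channel 2: kinship confirmation
# ---------------------------------------------------------------------------

def kinship_confirm(
    candidates: dict[str, set[str]],
    evidence: list[SampleEvidence],
    registry: Registry,
    tau: float = 0.1,
    floor: float = 0.02,
) -> dict[str, str | None]:
    """Confirm one candidate per sample from observed-vs-expected kinship.

    A hit supports candidate ``c`` when it links the sample to a known
    relative of ``c`` with ``phi_hat > floor`` and
    ``|phi_hat - phi_exp| <= tau``. A sample is confirmed only when
    exactly one candidate in its exclusion set is supported; support for
    multiple candidates is ambiguous and confirms none.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if floor < 0:
        raise ValueError("floor must be non-negative")
    known_relatives = registry.relative_ids()
    confirmed: dict[str, str | None] = {}
    for ev in evidence:
        for hit in ev.kinship_hits:
            if hit.relative_id not in known_relatives:
                raise KeyError(
                    f"kinship hit for {ev.biosample} references unknown "
                    f"relative {hit.relative_id!r}"
                )
        supported = set()
        for name in candidates.get(ev.biosample, set()):
            for link in registry[name].relatives:
                for hit in ev.kinship_hits:
                    if (
                        hit.relative_id == link.relative_id
                        and hit.phi_hat > floor
                        and abs(hit.phi_hat - link.phi_exp) <= tau
                    ):
                        supported.add(name)
        confirmed[ev.biosample] = supported.pop() if len(supported) == 1 else None
    return confirmed


# ---------------------------------------------------------------------------
# channel combination + uniqueness
# ---------------------------------------------------------------------------

def assign_identities(
    candidates: dict[str, set[str]],
    confirmations: dict[str, str | None],
    evidence: list[SampleEvidence],
    registry: Registry,
) -> IdentityAssignment:
    """Intersect the three channels per sample and enforce uniqueness.

    Per sample the exclusion set is intersected with the kinship-confirmed
    candidate and the records candidate where present; a channel that
    empties the intersection marks a conflict. Singleton intersections are
    assigned first (propagating removals in deterministic biosample
    order); remaining samples go through maximum bipartite matching, and
    any sample still holding several candidates is left unresolved.
    """
    ev_by_id = {ev.biosample: ev for ev in evidence}
    inter: dict[str, set[str]] = {}
    flags: dict[str, str] = {}
    for b in sorted(ev_by_id):
        ev = ev_by_id[b]
        cur = set(candidates.get(b, set()))
        conflict = False
        for channel_cand in (confirmations.get(b), ev.records_candidate):
            if channel_cand is None:
                continue
            if channel_cand in cur:
                cur = {channel_cand}
            else:
                conflict = True
        if conflict:
            flags[b] = CONFLICT
            inter[b] = set()
        else:
            inter[b] = cur

    assigned: dict[str, str] = {}
    taken: set[str] = set()

    # singleton propagation
    changed = True
    while changed:
        changed = False
        for b in sorted(inter):
            if b in assigned or flags.get(b) == CONFLICT:
                continue
            live = inter[b] - taken
            if len(live) == 1:
                name = next(iter(live))
                assigned[b] = name
                taken.add(name)
                changed = True

    # bipartite matching over what is left: assign only FORCED pairings,
    # i.e. edges present in every maximum matching; anything the matching
    # could permute is genuinely ambiguous and stays unresolved
    remaining = [
        b for b in sorted(inter)
        if b not in assigned and flags.get(b) != CONFLICT and inter[b] - taken
    ]
    if remaining:
        edges = [
            (("s", b), ("i", name))
            for b in remaining
            for name in sorted(inter[b] - taken)
        ]
        graph = nx.Graph(edges)
        top = [("s", b) for b in remaining]

        def match_size(g):
            return len(nx.bipartite.maximum_matching(
                g, top_nodes=[n for n in top if n in g]
            )) // 2

        base = match_size(graph)
        for u, v in edges:
            pruned = graph.copy()
            pruned.remove_edge(u, v)
            pruned.remove_nodes_from([n for n in (u, v) if pruned.degree(n) == 0])
            if match_size(pruned) < base:
                assigned[u[1]] = v[1]

    out: dict[str, Assignment] = {}
    for b in sorted(ev_by_id):
        ev = ev_by_id[b]
        name = assigned.get(b)
        if flags.get(b) == CONFLICT:
            flag = CONFLICT
        elif name is None:
            flag = UNRESOLVED
        else:
            agrees = [name in candidates.get(b, set())]
            if ev.kinship_hits:
                agrees.append(confirmations.get(b) == name)
            if ev.records_candidate is not None:
                agrees.append(ev.records_candidate == name)
            flag = FULL_CONCORDANCE if all(agrees) else PARTIAL
        out[b] = Assignment(
            biosample=b,
            individual=name,
            lab_id=ev.records_lab_id,
            flag=flag,
            candidate_set=tuple(sorted(candidates.get(b, set()))),
            kinship_candidate=confirmations.get(b),
            records_candidate=ev.records_candidate,
            sex_call=ev.sex_call,
            species_call=ev.species_call,
        )
    return IdentityAssignment(assignments=out)


def resolve_identities(
    evidence: list[SampleEvidence],
    registry: Registry,
    tau: float = 0.1,
    floor: float = 0.02,
) -> IdentityAssignment:
    """Convenience wrapper chaining the three channels."""
    cands = candidate_sets(evidence, registry)
    confirmed = kinship_confirm(cands, evidence, registry, tau=tau, floor=floor)
    return assign_identities(cands, confirmed, evidence, registry)


def corrected_lab_id(assignment: Assignment, reported_lab_id: str | None):
    """Final corrected lab id: the records value where present, the
    reported id where the channel is silent, None where invalidated."""
    if assignment.lab_id is None:
        return reported_lab_id
    if assignment.lab_id is LAB_ID_UNKNOWN:
        return None
    return assignment.lab_id


# ---------------------------------------------------------------------------
# discrepancy summary
# ---------------------------------------------------------------------------

def summarize(
    assignment: IdentityAssignment,
    reported: list[SampleRecord],
    registry: Registry,
) -> DiscrepancySummary:
    """Count label corrections implied by the assignment.

    ``n_relabelled``: samples whose assigned individual or corrected lab
    id differs from the reported one (a reported lab id invalidated by
    the records review counts as differing). ``n_misattributed``: the
    subset where the individual itself changed. ``n_sex_contradicted``:
    distinct reported names whose reported sex contradicts that
    individual's registry sex. Unresolved/conflicted samples are excluded
    from the first two counts and reported separately.
    """
    rep_by_id = {r.biosample: r for r in reported}
    n_relab = n_misattr = n_unres = 0
    for b, a in assignment.assignments.items():
        rep = rep_by_id[b]
        if a.individual is None:
            n_unres += 1
            continue
        misattr = a.individual != rep.name
        lab_changed = corrected_lab_id(a, rep.lab_id) != rep.lab_id
        if misattr:
            n_misattr += 1
        if misattr or lab_changed:
            n_relab += 1
    sex_contra = {
        r.name
        for r in reported
        if r.name in registry and registry[r.name].sex != r.sex
    }
    return DiscrepancySummary(
        n_relabelled=n_relab,
        n_misattributed=n_misattr,
        n_sex_contradicted=len(sex_contra),
        n_unresolved=n_unres,
    )
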