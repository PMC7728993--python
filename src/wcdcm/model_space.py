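"""Enumeration of DCM model spaces and family partitions.

A model space over l regions and one modulatory input assigns to every
directed inter-regional connection one of three states — absent, present,
or present-and-modulated — and lets each region independently receive or
not the driving input; self-connections are always present and never
modulated. The full space therefore counts 3**(l*(l-1)) * 2**l models.

The hypothesis-constrained space fixes the driving input to a single
designated region and keeps a model only if every other region is
reachable from the input region through present connections (the input
must be able to propagate to the whole network). For l = 3 this leaves
540 models. The reachability rule is inferred from the size of the
published space rather than stated alongside it; the derivation is in the
methods documentation.

Enumeration order is lexicographic over edge states, so model indices are
reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .neuronal import ModelSpec

__all__ = ["ModelSpace", "FamilyPartition", "enumerate_full",
           "enumerate_input_constrained", "partition_families"]

ABSENT, PRESENT, MODULATED = 0, 1, 2


@dataclass
class ModelSpace:
    """An ordered collection of ModelSpecs sharing regions and inputs."""

    specs: list
    rule: str
    family_labels: list | None = None

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, i):
        return self.specs[i]

    def __iter__(self):
        return iter(self.specs)


@dataclass
class FamilyPartition:
    """Total partition of a model space into named families."""

    labels: list          # family label per model index
    families: list        # distinct family labels, stable order

    def __post_init__(self):
        missing = {x for x in self.labels} - set(self.families)
        if missing:
            raise InvalidParameterError(f"labels not in family list: {missing}")

    def members(self, family) -> list:
        return [i for i, lab in enumerate(self.labels) if lab == family]


def _edges(l: int) -> list:
    """Directed inter-regional (target, source) pairs, lexicographic."""
    return [(i, j) for i in range(l) for j in range(l) if i != j]


def _spec_from_assignment(l, region_names, edge_states, input_mask,
                          variant, states):
    """Build a ModelSpec from per-edge states and a driving-input mask.

    Input 1 is the driving input, input 2 the modulatory (contextual) one.
    """
    A_mask = np.eye(l, dtype=bool)
    B_masks = np.zeros((2, l, l), dtype=bool)
    C_mask = np.zeros((l, 2), dtype=bool)
    C_mask[:, 0] = input_mask
    for (i, j), st in zip(_edges(l), edge_states):
        if st != ABSENT:
            A_mask[i, j] = True
        if st == MODULATED:
            B_masks[1, i, j] = True
    return ModelSpec(region_names, A_mask, B_masks, C_mask,
                     variant=variant, states=states)


def enumerate_full(l: int, m: int = 1, region_names=None,
                   variant: str = "bilinear",
                   states: str = "one") -> ModelSpace:
    """All models over l regions with one modulatory input.

    Every directed inter-regional connection independently takes one of
    {absent, present, present+modulated}; every region independently
    receives or not the driving input. Count: ``3**(l*(l-1)) * 2**l``.
    """
    if l < 1:
        raise InvalidParameterError("need at least one region")
    if m != 1:
        raise InvalidParameterError("full enumeration is defined for one "
                                    "modulatory input")
    if region_names is None:
        region_names = tuple(f"R{i + 1}" for i in range(l))
    edges = _edges(l)
    specs = []
    for edge_states in itertools.product((ABSENT, PRESENT, MODULATED),
                                         repeat=len(edges)):
        for input_bits in itertools.product((False, True), repeat=l):
            specs.append(_spec_from_assignment(
                l, region_names, edge_states, np.array(input_bits),
                variant, states))
    return ModelSpace(specs=specs, rule=f"full l={l} m=1")


def _reachable_from(l: int, present: set, source: int) -> bool:
    """True iff every region is reachable from ``source`` via present edges."""
    seen = {source}
    frontier = [source]
    while frontier:
        j = frontier.pop()
        for (tgt, src) in present:
            if src == j and tgt not in seen:
                seen.add(tgt)
                frontier.append(tgt)
    return len(seen) == l


def enumerate_input_constrained(l: int, input_region: int = 0,
                                region_names=None,
                                variant: str = "bilinear",
                                states: str = "one") -> ModelSpace:
    """Models with the driving input fixed to ``input_region`` (0-based),
    keeping only those in which every other region is reachable from the
    input region through present connections."""
    if l < 1:
        raise InvalidParameterError("need at least one region")
    if not 0 <= input_region < l:
        raise InvalidParameterError(f"input_region {input_region} out of range")
    if region_names is None:
        region_names = tuple(f"R{i + 1}" for i in range(l))
    edges = _edges(l)
    input_mask = np.zeros(l, dtype=bool)
    input_mask[input_region] = True
    specs = []
    for edge_states in itertools.product((ABSENT, PRESENT, MODULATED),
                                         repeat=len(edges)):
        present = {e for e, st in zip(edges, edge_states) if st != ABSENT}
        if not _reachable_from(l, present, input_region):
            continue
        specs.append(_spec_from_assignment(
            l, region_names, edge_states, input_mask, variant, states))
    return ModelSpace(specs=specs,
                      rule=f"input-constrained l={l} input={input_region}")


def partition_families(space: ModelSpace, predicate) -> FamilyPartition:
    """Partition ``space`` by the value of ``predicate(spec)``.

    The canonical use is the two-family split by neuronal variant over a
    duplicated structure space: ``predicate=lambda s: s.variant``.
    """
    labels = [predicate(s) for s in space]
    families = []
    for lab in labels:
        if lab not in families:
            families.append(lab)
    return FamilyPartition(labels=labels, families=families)
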