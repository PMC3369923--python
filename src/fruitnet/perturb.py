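"""Perturbation sets: assignments of genes to knockout or over-expression.

A knockout clamps a gene at the minimum of its observed expression range,
over-expression at the maximum; genes not listed stay wild-type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Tuple

KO = "KO"
OE = "OE"
WT = "WT"
MODES = (KO, OE)


@dataclass(frozen=True)
class PerturbationSet:
    """Immutable gene -> {KO, OE} assignment; absent genes are wild-type."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for gene, mode in dict(self.assignments).items():
            if mode == WT:
                continue  # explicit wild-type entries are dropped
            if mode not in MODES:
                raise ValueError(f"unknown perturbation mode {mode!r} for {gene!r}")
            clean[str(gene)] = mode
        object.__setattr__(self, "assignments", clean)

    @classmethod
    def coerce(cls, obj) -> "PerturbationSet":
        if isinstance(obj, cls):
            return obj
        if isinstance(obj, Mapping):
            return cls(dict(obj))
        # iterable of (gene, mode) pairs
        return cls(dict(obj))

    def genes(self) -> Tuple[str, ...]:
        return tuple(self.assignments)

    def items(self) -> Iterable[Tuple[str, str]]:
        return self.assignments.items()

    def __len__(self) -> int:
        return len(self.assignments)

    def __bool__(self) -> bool:
        return bool(self.assignments)

    def with_gene(self, gene: str, mode: str) -> "PerturbationSet":
        """Copy with `gene` set to KO/OE, or reverted to wild-type."""
        new = dict(self.assignments)
        if mode == WT:
            new.pop(gene, None)
        else:
            new[gene] = mode
        return PerturbationSet(new)

    def validate_against(self, known_genes) -> None:
        known = set(known_genes)
        for gene in self.assignments:
            if gene not in known:
                raise KeyError(f"perturbed gene {gene!r} not in the model")

    def label(self) -> str:
        if not self.assignments:
            return "WT"
        return "+".join(f"{g}:{m}" for g, m in sorted(self.assignments.items()))
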