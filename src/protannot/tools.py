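"""Composition and region arithmetic shared by the analyses.

Simple amino-acid fraction computations (the "fraction of the chemistry of
interest" over a sequence or domain), interval overlap on 1-based inclusive
coordinates, and per-residue domain context lookup.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Set, Union

import numpy as np

from .core import (
    BUILTIN_CLASSES,
    Domain,
    Protein,
    ResidueClass,
    resolve_residue_class,
)
from .exceptions import BoundsError, EmptyRegionError


def fraction_of_class(
    sequence_or_region: Union[str, Domain],
    residue_class: Union[str, ResidueClass, Iterable[str]],
) -> float:
    """Fraction of residues belonging to a residue class, in [0, 1].

    Accepts a raw sequence string or an attached Domain. Input is uppercased
    on entry; characters are never silently skipped, so the denominator is
    always the full region length.
    """
    if isinstance(sequence_or_region, Domain):
        seq = sequence_or_region.sequence
    else:
        seq = str(sequence_or_region)
    seq = seq.upper()
    if len(seq) == 0:
        raise EmptyRegionError("cannot compute a composition fraction of an empty region")
    members = resolve_residue_class(residue_class).members
    return sum(1 for ch in seq if ch in members) / len(seq)


def fraction_of_classes(
    sequence_or_region: Union[str, Domain],
    residue_classes: Sequence[Union[str, ResidueClass, Iterable[str]]],
) -> float:
    """Summed fraction over several residue classes (e.g. charged + aliphatic).

    The built-in classes are disjoint, so the sum equals the fraction of the
    union for them; overlapping ad-hoc classes are summed as given.
    """
    return sum(fraction_of_class(sequence_or_region, c) for c in residue_classes)


def composition_vector(sequence_or_region: Union[str, Domain]) -> dict:
    """Per-class fractions over the built-in classes plus the 'other'
    complement (C, H and any extended letters); values sum to 1."""
    fractions = {
        label: fraction_of_class(sequence_or_region, cls)
        for label, cls in BUILTIN_CLASSES.items()
    }
    fractions["other"] = 1.0 - sum(fractions.values())
    # guard against tiny negative float residue
    if abs(fractions["other"]) < 1e-12:
        fractions["other"] = 0.0
    return fractions


def domain_overlap(a: Domain, b: Domain) -> int:
    """Number of residues covered by both domains (inclusive intervals);
    0 when disjoint. Symmetric and bounded by min(len(a), len(b))."""
    return max(0, min(a.stop, b.stop) - max(a.start, b.start) + 1)


def residue_context(protein: Protein, position: int) -> Set[str]:
    """The set of domain types covering a 1-based position (empty set when
    the residue is uncovered)."""
    position = int(position)
    if position < 1 or position > len(protein):
        raise BoundsError(
            f"position {position} outside [1, {len(protein)}] on '{protein.unique_id}'"
        )
    return {d.domain_type for d in protein.domains if d.start <= position <= d.stop}


def domain_coverage_mask(protein: Protein, domain_type: str) -> np.ndarray:
    """Boolean array of length len(protein); True where any domain of the
    given type covers the residue (0-based index i = residue i+1)."""
    mask = np.zeros(len(protein), dtype=bool)
    for d in protein.get_domains_by_type(domain_type):
        mask[d.start - 1 : d.stop] = True
    return mask


def covered_residue_count(protein: Protein, domain_type: str) -> int:
    """Number of residues covered by at least one domain of the given type."""
    return int(domain_coverage_mask(protein, domain_type).sum())


def disorder_fraction(protein: Protein, idr_domain_type: str = "IDR") -> float:
    """Fraction of the protein covered by domains of the given (IDR) type."""
    return covered_residue_count(protein, idr_domain_type) / len(protein)
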