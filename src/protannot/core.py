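"""Hierarchical protein annotation data model.

The object hierarchy is Proteome -> Protein -> {Domain, Site, Track}:

* a :class:`Proteome` is an insertion-ordered collection of Proteins keyed by
  a unique identifier, plus free-form proteome-level attributes;
* a :class:`Protein` holds one amino-acid sequence and all annotations
  attached to it;
* a :class:`Domain` is a contiguous subregion ``[start, stop]`` (1-based,
  inclusive at both ends) with a type label, e.g. an intrinsically
  disordered region (IDR) or a Pfam domain;
* a :class:`Site` is a single-residue annotation, e.g. a phosphorylation
  site, with a type, a symbol and a numeric value;
* a :class:`Track` is a per-residue vector (numeric or symbolic) exactly as
  long as the sequence, e.g. relative solvent accessibility.

Every attachment is bounds-checked against the parent sequence, so any object
reachable from a Proteome is internally consistent by construction. All
iteration orders are insertion orders; nothing depends on hash ordering.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .exceptions import (
    AlphabetError,
    BoundsError,
    CoordinateOrderError,
    DuplicateIDError,
    DuplicateTrackError,
    EmptyRegionError,
    MissingTrackError,
    TrackLengthError,
)

#: The 20 canonical amino acids.
CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Extra letters accepted under the permissive alphabet (unknown residue X,
#: selenocysteine U).
EXTENDED_LETTERS = frozenset("XU")


class ResidueClass:
    """A named set of amino-acid letters, e.g. the polar residues.

    The built-in classes (module-level constants below) follow the
    convention used for classifying the chemistry of disordered regions:
    proline is grouped with the polar residues, histidine and cysteine
    belong to no class, and histidine is *not* counted as charged.
    """

    __slots__ = ("label", "members")

    def __init__(self, label: str, members: Iterable[str]):
        members = frozenset(str(m).upper() for m in members)
        if not label:
            raise ValueError("residue class label must be non-empty")
        if not members:
            raise ValueError("residue class must have at least one member")
        bad = members - CANONICAL_ALPHABET - EXTENDED_LETTERS
        if bad:
            raise ValueError(f"residue class members outside alphabet: {sorted(bad)}")
        self.label = label
        self.members = members

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self.members

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ResidueClass({self.label!r}, {''.join(sorted(self.members))!r})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ResidueClass)
            and self.label == other.label
            and self.members == other.members
        )

    def __hash__(self) -> int:
        return hash((self.label, self.members))


POLAR = ResidueClass("polar", "GSTQNP")
AROMATIC = ResidueClass("aromatic", "FWY")
ALIPHATIC = ResidueClass("aliphatic", "AILMV")
CHARGED = ResidueClass("charged", "DEKR")

#: Built-in residue classes, keyed by label. Cysteine and histidine fall in
#: none of them; bookkeeping code may treat the complement as an implicit
#: "other" class.
BUILTIN_CLASSES: Dict[str, ResidueClass] = {
    c.label: c for c in (POLAR, AROMATIC, ALIPHATIC, CHARGED)
}


def resolve_residue_class(cls: Union[str, ResidueClass, Iterable[str]]) -> ResidueClass:
    """Coerce a class label, a ResidueClass, or a bare letter set to a ResidueClass."""
    if isinstance(cls, ResidueClass):
        return cls
    if isinstance(cls, str):
        if cls in BUILTIN_CLASSES:
            return BUILTIN_CLASSES[cls]
        # A bare string of residue letters ("RK") is accepted as an ad-hoc class.
        return ResidueClass(cls, cls)
    members = list(cls)
    return ResidueClass("+".join(sorted(members)), members)


class Domain:
    """A contiguous region ``[start, stop]`` of a protein, 1-based inclusive."""

    __slots__ = ("start", "stop", "domain_type", "attributes", "protein")

    def __init__(
        self,
        start: int,
        stop: int,
        domain_type: str,
        attributes: Optional[Mapping[str, str]] = None,
        protein: Optional["Protein"] = None,
    ):
        self.start = int(start)
        self.stop = int(stop)
        self.domain_type = str(domain_type)
        self.attributes: Dict[str, str] = dict(attributes or {})
        self.protein = protein

    def __len__(self) -> int:
        return self.stop - self.start + 1

    @property
    def sequence(self) -> str:
        """The amino-acid subsequence this domain covers."""
        if self.protein is None:
            raise ValueError("domain is not attached to a protein")
        return self.protein.sequence[self.start - 1 : self.stop]

    def __repr__(self) -> str:
        return f"Domain({self.start}, {self.stop}, {self.domain_type!r})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Domain)
            and (self.start, self.stop, self.domain_type, self.attributes)
            == (other.start, other.stop, other.domain_type, other.attributes)
        )

    def __hash__(self):
        return id(self)


class Site:
    """A single-residue annotation (e.g. a post-translational modification)."""

    __slots__ = ("position", "site_type", "symbol", "value", "attributes", "protein")

    def __init__(
        self,
        position: int,
        site_type: str,
        symbol: str = "",
        value: float = 1.0,
        attributes: Optional[Mapping[str, str]] = None,
        protein: Optional["Protein"] = None,
    ):
        self.position = int(position)
        self.site_type = str(site_type)
        self.symbol = str(symbol)
        self.value = float(value)
        self.attributes: Dict[str, str] = dict(attributes or {})
        self.protein = protein

    def __repr__(self) -> str:
        return f"Site({self.position}, {self.site_type!r}, {self.symbol!r}, {self.value})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Site)
            and (self.position, self.site_type, self.symbol, self.attributes) ==
            (other.position, other.site_type, other.symbol, other.attributes)
            and math.isclose(self.value, other.value, rel_tol=0, abs_tol=0.0)
        )

    def __hash__(self):
        return id(self)


class Track:
    """A per-residue vector annotation, numeric ("values") or symbolic ("symbols").

    The payload is stored as an immutable tuple exactly as long as the parent
    sequence; element ``i`` (0-based) annotates residue ``i + 1`` (1-based).
    """

    __slots__ = ("name", "_payload", "kind")

    def __init__(
        self,
        name: str,
        values: Optional[Sequence[float]] = None,
        symbols: Optional[Sequence[str]] = None,
    ):
        if not name:
            raise ValueError("track name must be non-empty")
        if (values is None) == (symbols is None):
            raise ValueError("exactly one of values/symbols must be given")
        self.name = str(name)
        if values is not None:
            payload = tuple(float(v) for v in values)
            for i, v in enumerate(payload):
                if not math.isfinite(v):
                    raise ValueError(
                        f"track '{name}' has non-finite value {v!r} at residue {i + 1}"
                    )
            self.kind = "values"
        else:
            payload = tuple(str(s) for s in symbols)
            for i, s in enumerate(payload):
                if not s or "\t" in s or " " in s:
                    raise ValueError(
                        f"track '{name}' has invalid symbol {s!r} at residue {i + 1}"
                    )
            self.kind = "symbols"
        self._payload = payload

    @property
    def payload(self) -> tuple:
        return self._payload

    @property
    def values(self) -> Tuple[float, ...]:
        if self.kind != "values":
            raise TypeError(f"track '{self.name}' is a symbols track")
        return self._payload

    @property
    def symbols(self) -> Tuple[str, ...]:
        if self.kind != "symbols":
            raise TypeError(f"track '{self.name}' is a values track")
        return self._payload

    def __len__(self) -> int:
        return len(self._payload)

    def region(self, start: int, stop: int) -> tuple:
        """Payload slice for residues ``start..stop`` (1-based inclusive)."""
        return self._payload[start - 1 : stop]

    def __repr__(self) -> str:
        return f"Track({self.name!r}, kind={self.kind}, len={len(self)})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Track)
            and self.name == other.name
            and self.kind == other.kind
            and self._payload == other._payload
        )

    def __hash__(self):
        return id(self)


def _check_region(start: int, stop: int, length: int) -> None:
    if start > stop:
        raise CoordinateOrderError(f"inverted region: start {start} > stop {stop}")
    if start < 1 or stop > length:
        raise BoundsError(
            f"region [{start}, {stop}] outside sequence bounds [1, {length}]"
        )


class Protein:
    """One amino-acid sequence plus its domains, sites and tracks.

    Coordinates throughout are 1-based and inclusive at both ends: residue 1
    is the first residue and a domain ``[start, stop]`` covers
    ``stop - start + 1`` residues. Sites may share a position and domains may
    overlap; track names are unique per protein.
    """

    def __init__(
        self,
        unique_id: str,
        sequence: str,
        name: str = "",
        attributes: Optional[Mapping[str, str]] = None,
        allow_extended: bool = False,
    ):
        if not unique_id:
            raise ValueError("unique_id must be a non-empty string")
        sequence = str(sequence).upper()
        if len(sequence) < 1:
            raise ValueError(f"protein '{unique_id}' has an empty sequence")
        alphabet = CANONICAL_ALPHABET | (EXTENDED_LETTERS if allow_extended else set())
        for i, ch in enumerate(sequence):
            if ch not in alphabet:
                raise AlphabetError(ch, i + 1, unique_id)
        self.unique_id = str(unique_id)
        self.name = str(name)
        self._sequence = sequence
        self.attributes: Dict[str, str] = dict(attributes or {})
        self._domains: List[Domain] = []
        self._sites_by_pos: Dict[int, List[Site]] = {}
        self._site_list: List[Site] = []
        self._tracks: Dict[str, Track] = {}

    # -- identity ---------------------------------------------------------

    @property
    def sequence(self) -> str:
        return self._sequence

    def __len__(self) -> int:
        return len(self._sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        _check_region(position, position, len(self))
        return self._sequence[position - 1]

    def __repr__(self) -> str:
        return f"Protein({self.unique_id!r}, len={len(self)})"

    # -- domains ----------------------------------------------------------

    def add_domain(
        self,
        start: int,
        stop: int,
        domain_type: str,
        attributes: Optional[Mapping[str, str]] = None,
        safe: bool = True,
    ) -> Domain:
        """Attach a domain ``[start, stop]`` of the given type.

        With ``safe=True`` (default) out-of-bounds coordinates raise
        :class:`BoundsError`. With ``safe=False`` coordinates are clipped to
        ``[1, len]`` — useful when annotations were generated against a
        slightly different sequence version. Inverted coordinates
        (start > stop) always raise :class:`CoordinateOrderError`.
        """
        start, stop = int(start), int(stop)
        if not domain_type:
            raise ValueError("domain_type must be non-empty")
        if start > stop:
            raise CoordinateOrderError(
                f"inverted domain coordinates: start {start} > stop {stop}"
            )
        n = len(self)
        if start < 1 or stop > n:
            if safe:
                raise BoundsError(
                    f"domain [{start}, {stop}] outside [1, {n}] "
                    f"on protein '{self.unique_id}'"
                )
            start = min(max(start, 1), n)
            stop = min(max(stop, 1), n)
        dom = Domain(start, stop, domain_type, attributes, protein=self)
        self._domains.append(dom)
        return dom

    @property
    def domains(self) -> List[Domain]:
        return list(self._domains)

    def get_domains_by_type(self, domain_type: str) -> List[Domain]:
        """All domains whose type matches exactly, in insertion order."""
        return [d for d in self._domains if d.domain_type == domain_type]

    # -- sites ------------------------------------------------------------

    def add_site(
        self,
        position: int,
        site_type: str,
        symbol: str = "",
        value: float = 1.0,
        attributes: Optional[Mapping[str, str]] = None,
    ) -> Site:
        """Attach a site at a 1-based position; co-located sites are allowed."""
        position = int(position)
        if not site_type:
            raise ValueError("site_type must be non-empty")
        if position < 1 or position > len(self):
            raise BoundsError(
                f"site position {position} outside [1, {len(self)}] "
                f"on protein '{self.unique_id}'"
            )
        value = float(value)
        if not math.isfinite(value):
            raise ValueError(f"site value must be finite, got {value!r}")
        site = Site(position, site_type, symbol, value, attributes, protein=self)
        self._sites_by_pos.setdefault(position, []).append(site)
        self._site_list.append(site)
        return site

    @property
    def sites(self) -> List[Site]:
        """All sites in insertion order."""
        return list(self._site_list)

    def sites_at(self, position: int) -> List[Site]:
        """Sites at one position, in insertion order."""
        return list(self._sites_by_pos.get(int(position), []))

    def get_sites_by_type(self, site_type: str) -> List[Site]:
        return [s for s in self._site_list if s.site_type == site_type]

    def sites_in_region(
        self, start: int, stop: int, site_type: Optional[str] = None
    ) -> List[Site]:
        """Sites with ``start <= position <= stop`` (boundaries included),
        optionally restricted to one site type, in insertion order."""
        _check_region(int(start), int(stop), len(self))
        out = [s for s in self._site_list if start <= s.position <= stop]
        if site_type is not None:
            out = [s for s in out if s.site_type == site_type]
        return out

    def site_positions(self, site_type: Optional[str] = None) -> Set[int]:
        """Set of positions carrying at least one site (of the given type)."""
        if site_type is None:
            return set(self._sites_by_pos)
        return {s.position for s in self._site_list if s.site_type == site_type}

    # -- tracks -----------------------------------------------------------

    def add_track(
        self,
        name: str,
        values: Optional[Sequence[float]] = None,
        symbols: Optional[Sequence[str]] = None,
    ) -> Track:
        """Attach a per-residue track; payload must match the sequence length."""
        if name in self._tracks:
            raise DuplicateTrackError(
                f"track '{name}' already exists on protein '{self.unique_id}'"
            )
        track = Track(name, values=values, symbols=symbols)
        if len(track) != len(self):
            raise TrackLengthError(len(self), len(track), name)
        self._tracks[name] = track
        return track

    @property
    def tracks(self) -> Dict[str, Track]:
        return dict(self._tracks)

    def track(self, name: str) -> Track:
        if name not in self._tracks:
            raise MissingTrackError(
                f"protein '{self.unique_id}' has no track '{name}'"
            )
        return self._tracks[name]

    def has_track(self, name: str) -> bool:
        return name in self._tracks

    def extract_track_region(self, track_name: str, start: int, stop: int) -> tuple:
        """Track payload for residues ``start..stop``; element 1 annotates
        residue ``start``."""
        track = self.track(track_name)
        _check_region(int(start), int(stop), len(self))
        return track.region(int(start), int(stop))


class Proteome:
    """The root container: an insertion-ordered map unique_id -> Protein.

    Parameters
    ----------
    attributes
        Free-form proteome-level string attributes.
    duplicate_policy
        ``"strict"`` (default): adding an existing unique_id raises
        :class:`DuplicateIDError`. ``"skip"``: the first protein wins and the
        duplicate add is ignored (returned protein is the existing one).
    allow_extended
        Accept the letters X and U in sequences in addition to the 20
        canonical residues. Off by default so typos fail loudly.
    """

    def __init__(
        self,
        attributes: Optional[Mapping[str, str]] = None,
        duplicate_policy: str = "strict",
        allow_extended: bool = False,
    ):
        if duplicate_policy not in ("strict", "skip"):
            raise ValueError("duplicate_policy must be 'strict' or 'skip'")
        self.attributes: Dict[str, str] = dict(attributes or {})
        self.duplicate_policy = duplicate_policy
        self.allow_extended = allow_extended
        self._proteins: Dict[str, Protein] = {}

    def add_protein(
        self,
        unique_id: str,
        sequence: str,
        name: str = "",
        attributes: Optional[Mapping[str, str]] = None,
    ) -> Protein:
        """Create and register a Protein; returns it.

        Under the ``skip`` duplicate policy a repeated unique_id returns the
        already-registered protein unchanged.
        """
        if unique_id in self._proteins:
            if self.duplicate_policy == "strict":
                raise DuplicateIDError(f"protein '{unique_id}' already exists")
            return self._proteins[unique_id]
        protein = Protein(
            unique_id,
            sequence,
            name=name,
            attributes=attributes,
            allow_extended=self.allow_extended,
        )
        self._proteins[unique_id] = protein
        return protein

    def remove_protein(self, unique_id: str) -> None:
        if unique_id not in self._proteins:
            raise KeyError(unique_id)
        del self._proteins[unique_id]

    def protein(self, unique_id: str) -> Protein:
        return self._proteins[unique_id]

    def __contains__(self, unique_id: str) -> bool:
        return unique_id in self._proteins

    def __len__(self) -> int:
        return len(self._proteins)

    def __iter__(self) -> Iterator[Protein]:
        return iter(self._proteins.values())

    @property
    def proteins(self) -> List[Protein]:
        return list(self._proteins.values())

    @property
    def unique_ids(self) -> List[str]:
        return list(self._proteins.keys())

    def get_domains_by_type(self, domain_type: str) -> List[Domain]:
        """All matching domains across the proteome: protein insertion order,
        then domain insertion order."""
        out: List[Domain] = []
        for protein in self:
            out.extend(protein.get_domains_by_type(domain_type))
        return out

    def __repr__(self) -> str:
        return f"Proteome({len(self)} proteins)"
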