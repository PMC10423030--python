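"""Readers, writers and validators for FASTA and the tab-separated annotation files.

Four annotation file flavors exist, each storing one annotation per line with
tab-separated columns and optional trailing ``key:value`` attribute tokens:

================  =====================================================
flavor            columns
================  =====================================================
domains           unique_ID  start  stop  domain_type  [key:value ...]
sites             unique_ID  position  site_type  symbol  value  [key:value ...]
tracks            unique_ID  track_name  token_1 ... token_L   (L = protein length)
proteins          unique_ID  [key:value ...]   (protein-level attributes)
================  =====================================================

Lines starting with ``#`` are comments; blank lines are ignored; there is no
header row. Coordinates are 1-based inclusive, matching the in-memory model.
Attribute tokens split on the *first* ``:`` only, so values may contain
colons; keys may not contain ``:`` or tabs and must be unique per line.
Numeric values are serialized with ``repr``-level precision so that a
write/read round trip is exact.

Readers collect per-line problems into a :class:`ValidationReport` instead of
aborting on the first error: a fatal line is rejected atomically (none of its
annotation is applied) while the remaining lines are still processed.
"""

from __future__ import annotations

import io as _stdio
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from Bio import SeqIO

from .core import Proteome
from .exceptions import EmptyInputError, ParseError

FILE_KINDS = ("proteins", "domains", "sites", "tracks")

# machine-readable error codes
MISSING_COLUMNS = "MISSING_COLUMNS"
BAD_INT = "BAD_INT"
BAD_FLOAT = "BAD_FLOAT"
NON_FINITE = "NON_FINITE"
BAD_ATTRIBUTE = "BAD_ATTRIBUTE"
DUPLICATE_KEY = "DUPLICATE_KEY"
UNKNOWN_PROTEIN = "UNKNOWN_PROTEIN"
BOUNDS = "BOUNDS"
COORD_ORDER = "COORD_ORDER"
TRACK_LENGTH = "TRACK_LENGTH"
DUPLICATE_TRACK = "DUPLICATE_TRACK"
EMPTY_FIELD = "EMPTY_FIELD"


@dataclass
class ValidationReport:
    """Outcome of reading or validating one annotation file.

    ``n_lines`` counts data lines (comments and blank lines excluded);
    ``n_accepted + len(fatal errors) == n_lines``.
    """

    path: str = ""
    file_kind: str = ""
    n_lines: int = 0
    n_accepted: int = 0
    errors: List[Tuple[int, str, str]] = field(default_factory=list)
    warnings: List[Tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, lineno: int, code: str, message: str) -> None:
        self.errors.append((lineno, code, message))

    def add_warning(self, lineno: int, code: str, message: str) -> None:
        self.warnings.append((lineno, code, message))

    def summary(self) -> str:
        return (
            f"{self.path or '<stream>'} [{self.file_kind}]: "
            f"{self.n_accepted}/{self.n_lines} lines accepted, "
            f"{len(self.errors)} errors, {len(self.warnings)} warnings"
        )


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _iter_data_lines(path: str):
    """Yield (lineno, raw_line) for non-comment, non-blank lines.

    Opened in universal-newline text mode, so CRLF files parse identically
    to LF files.
    """
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_attribute_tokens(tokens, lineno, report):
    """Parse trailing ``key:value`` tokens; returns dict or None on fatal error."""
    attributes: Dict[str, str] = {}
    for token in tokens:
        key, sep, value = token.partition(":")
        if not sep or not key:
            report.add_error(
                lineno, BAD_ATTRIBUTE,
                f"malformed attribute token {token!r} (expected key:value)",
            )
            return None
        if key in attributes:
            report.add_error(lineno, DUPLICATE_KEY, f"duplicate attribute key {key!r}")
            return None
        attributes[key] = value
    return attributes


def _parse_int(token, lineno, what, report):
    try:
        return int(token)
    except ValueError:
        report.add_error(lineno, BAD_INT, f"{what} is not an integer: {token!r}")
        return None


def _parse_float(token, lineno, what, report):
    try:
        value = float(token)
    except ValueError:
        report.add_error(lineno, BAD_FLOAT, f"{what} is not a number: {token!r}")
        return None
    if not math.isfinite(value):
        report.add_error(lineno, NON_FINITE, f"{what} is not finite: {token!r}")
        return None
    return value


def _resolve_protein(unique_id, proteome, lineno, report, skip_unknown):
    if unique_id == "":
        report.add_error(lineno, EMPTY_FIELD, "empty unique_ID")
        return None
    if unique_id not in proteome:
        if skip_unknown:
            # well-formed but unapplied: recorded as a warning, not accepted
            report.add_warning(
                lineno, UNKNOWN_PROTEIN, f"protein '{unique_id}' not in proteome; line skipped"
            )
        else:
            report.add_error(lineno, UNKNOWN_PROTEIN, f"protein '{unique_id}' not in proteome")
        return None
    return proteome.protein(unique_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_UNIPROT_HEADER = re.compile(r"^[a-z]{2}\|([^|]+)\|")

ID_POLICIES = ("full", "first_token", "accession")


def _derive_id(header: str, id_policy: str) -> str:
    if id_policy == "full":
        return header.strip()
    first = header.split()[0] if header.split() else ""
    if id_policy == "first_token":
        return first
    if id_policy == "accession":
        m = _UNIPROT_HEADER.match(first)
        if m:
            return m.group(1)
        return first
    raise ValueError(f"unknown id_policy {id_policy!r}; choose from {ID_POLICIES}")


def read_fasta(
    path: str,
    proteome: Optional[Proteome] = None,
    id_policy: str = "first_token",
    **proteome_kwargs,
) -> Proteome:
    """Read a FASTA file into a (new or existing) Proteome.

    ``id_policy`` controls how the unique_ID is derived from each header:
    ``"full"`` keeps the whole header, ``"first_token"`` the first
    whitespace-separated token, and ``"accession"`` extracts the accession
    from UniProt-style ``db|ACCESSION|NAME`` headers (falling back to the
    first token). Duplicate identifiers follow the proteome's policy.
    """
    if proteome is None:
        proteome = Proteome(**proteome_kwargs)
    with open(path, "r", encoding="utf-8") as fh:
        content = fh.read()
    stripped = content.strip()
    if not stripped:
        raise EmptyInputError(f"FASTA file {path!r} contains no records")
    for lineno, line in enumerate(content.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
    for record in SeqIO.parse(_stdio.StringIO(content), "fasta"):
        header = record.description
        unique_id = _derive_id(header, id_policy)
        if not unique_id:
            raise ParseError(f"{path}: record with empty identifier (header {header!r})")
        if not str(record.seq):
            raise ParseError(f"{path}: record '{unique_id}' has an empty sequence")
        proteome.add_protein(unique_id, str(record.seq), name=header)
    return proteome


def write_fasta(proteome: Proteome, path: str, line_width: int = 60) -> None:
    """Write every protein as a FASTA record, unique_ID as the header."""
    with open(path, "w", encoding="utf-8") as fh:
        for protein in proteome:
            fh.write(f">{protein.unique_id}\n")
            seq = protein.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# per-kind line processors
# ---------------------------------------------------------------------------
#
# Each processor parses one data line and, when ``apply`` is true and the
# line is valid, attaches the annotation. Validation reuses exactly the same
# code path with ``apply=False`` plus a side-effect-free duplicate-track
# simulation, so validate/read can never disagree.

def _process_domains_line(tokens, lineno, proteome, report, apply, state, *,
                          safe=True, skip_unknown=True):
    if len(tokens) < 4:
        report.add_error(lineno, MISSING_COLUMNS,
                         f"domains line needs >= 4 columns, got {len(tokens)}")
        return False
    start = _parse_int(tokens[1], lineno, "start", report)
    stop = _parse_int(tokens[2], lineno, "stop", report)
    if start is None or stop is None:
        return False
    domain_type = tokens[3]
    if not domain_type:
        report.add_error(lineno, EMPTY_FIELD, "empty domain_type")
        return False
    attributes = _parse_attribute_tokens(tokens[4:], lineno, report)
    if attributes is None:
        return False
    protein = _resolve_protein(tokens[0], proteome, lineno, report, skip_unknown)
    if protein is None:
        return False
    if start > stop:
        report.add_error(lineno, COORD_ORDER,
                         f"inverted coordinates: start {start} > stop {stop}")
        return False
    n = len(protein)
    if (start < 1 or stop > n) and safe:
        report.add_error(lineno, BOUNDS,
                         f"domain [{start}, {stop}] outside [1, {n}] on '{protein.unique_id}'")
        return False
    if apply:
        protein.add_domain(start, stop, domain_type, attributes, safe=safe)
    return True


def _process_sites_line(tokens, lineno, proteome, report, apply, state, *,
                        skip_unknown=True):
    if len(tokens) < 5:
        report.add_error(lineno, MISSING_COLUMNS,
                         f"sites line needs >= 5 columns, got {len(tokens)}")
        return False
    position = _parse_int(tokens[1], lineno, "position", report)
    if position is None:
        return False
    site_type, symbol = tokens[2], tokens[3]
    if not site_type:
        report.add_error(lineno, EMPTY_FIELD, "empty site_type")
        return False
    value = _parse_float(tokens[4], lineno, "value", report)
    if value is None:
        return False
    attributes = _parse_attribute_tokens(tokens[5:], lineno, report)
    if attributes is None:
        return False
    protein = _resolve_protein(tokens[0], proteome, lineno, report, skip_unknown)
    if protein is None:
        return False
    if position < 1 or position > len(protein):
        report.add_error(lineno, BOUNDS,
                         f"position {position} outside [1, {len(protein)}] on '{protein.unique_id}'")
        return False
    if apply:
        protein.add_site(position, site_type, symbol, value, attributes)
    return True


def _process_tracks_line(tokens, lineno, proteome, report, apply, state, *,
                         mode="values", skip_unknown=True):
    if len(tokens) < 3:
        report.add_error(lineno, MISSING_COLUMNS,
                         f"tracks line needs >= 3 columns, got {len(tokens)}")
        return False
    track_name = tokens[1]
    if not track_name:
        report.add_error(lineno, EMPTY_FIELD, "empty track_name")
        return False
    payload_tokens = tokens[2:]
    if mode == "values":
        payload = []
        for j, token in enumerate(payload_tokens):
            v = _parse_float(token, lineno, f"track value {j + 1}", report)
            if v is None:
                return False
            payload.append(v)
    elif mode == "symbols":
        payload = list(payload_tokens)
        for j, s in enumerate(payload):
            if not s:
                report.add_error(lineno, EMPTY_FIELD, f"empty symbol at residue {j + 1}")
                return False
    else:
        raise ValueError("mode must be 'values' or 'symbols'")
    protein = _resolve_protein(tokens[0], proteome, lineno, report, skip_unknown)
    if protein is None:
        return False
    if not getattr(protein, "_any_length", False) and len(payload) != len(protein):
        report.add_error(lineno, TRACK_LENGTH,
                         f"track '{track_name}' has {len(payload)} residues but "
                         f"protein '{protein.unique_id}' has {len(protein)}")
        return False
    seen = state.setdefault("track_names", {}).setdefault(
        tokens[0], set(protein.tracks)
    )
    if track_name in seen:
        report.add_error(lineno, DUPLICATE_TRACK,
                         f"track '{track_name}' already defined on '{protein.unique_id}'")
        return False
    seen.add(track_name)
    if apply:
        if mode == "values":
            protein.add_track(track_name, values=payload)
        else:
            protein.add_track(track_name, symbols=payload)
    return True


def _process_proteins_line(tokens, lineno, proteome, report, apply, state, *,
                           skip_unknown=True):
    if len(tokens) < 1:
        report.add_error(lineno, MISSING_COLUMNS, "empty line")
        return False
    attributes = _parse_attribute_tokens(tokens[1:], lineno, report)
    if attributes is None:
        return False
    protein = _resolve_protein(tokens[0], proteome, lineno, report, skip_unknown)
    if protein is None:
        return False
    if apply:
        protein.attributes.update(attributes)
    return True


_PROCESSORS: Dict[str, Callable] = {
    "domains": _process_domains_line,
    "sites": _process_sites_line,
    "tracks": _process_tracks_line,
    "proteins": _process_proteins_line,
}


def _run(path, file_kind, proteome, apply, **kwargs) -> ValidationReport:
    processor = _PROCESSORS[file_kind]
    report = ValidationReport(path=str(path), file_kind=file_kind)
    state: dict = {}
    for lineno, line in _iter_data_lines(path):
        report.n_lines += 1
        tokens = line.split("\t")
        if processor(tokens, lineno, proteome, report, apply, state, **kwargs):
            report.n_accepted += 1
    return report


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------

def read_domains(
    path: str,
    proteome: Proteome,
    safe: bool = True,
    skip_unknown_protein: bool = True,
) -> ValidationReport:
    """Read a domains file onto an existing proteome.

    Lines naming proteins absent from the proteome are skipped with a warning
    by default (``skip_unknown_protein=False`` makes them fatal), which
    supports annotating a proteome subset. With ``safe=False`` out-of-bounds
    domains are clipped to the sequence instead of rejected.
    """
    return _run(path, "domains", proteome, apply=True,
                safe=safe, skip_unknown=skip_unknown_protein)


def read_sites(
    path: str,
    proteome: Proteome,
    skip_unknown_protein: bool = True,
) -> ValidationReport:
    """Read a sites file onto an existing proteome."""
    return _run(path, "sites", proteome, apply=True,
                skip_unknown=skip_unknown_protein)


def read_tracks(
    path: str,
    proteome: Proteome,
    mode: str = "values",
    skip_unknown_protein: bool = True,
) -> ValidationReport:
    """Read a tracks file; ``mode`` selects numeric ('values') or symbolic
    ('symbols') parsing for the whole file."""
    return _run(path, "tracks", proteome, apply=True,
                mode=mode, skip_unknown=skip_unknown_protein)


def read_protein_attributes(
    path: str,
    proteome: Proteome,
    skip_unknown_protein: bool = True,
) -> ValidationReport:
    """Read protein-level key:value attributes (e.g. abundances)."""
    return _run(path, "proteins", proteome, apply=True,
                skip_unknown=skip_unknown_protein)


def validate_file(
    path: str,
    file_kind: str,
    proteome: Optional[Proteome] = None,
    mode: str = "values",
) -> ValidationReport:
    """Classify every line of a file as accepted / warning / fatal without
    mutating anything.

    Without a proteome only schema-level checks run (column counts, numeric
    fields, attribute syntax); with one, coordinate bounds, track lengths and
    unknown-protein checks run as well. Validation uses the same line
    processors as the readers with application disabled, so it is idempotent
    and side-effect free by construction.
    """
    if file_kind not in FILE_KINDS:
        raise ValueError(f"file_kind must be one of {FILE_KINDS}, got {file_kind!r}")
    if proteome is None:
        proteome = _PermissiveProteome()
    kwargs = {"skip_unknown": True}
    if file_kind == "tracks":
        kwargs["mode"] = mode
    return _run(path, file_kind, proteome, apply=False, **kwargs)


class _AnyLengthProtein:
    """Stand-in protein used when validating without a proteome: any
    coordinate and any track length is considered in-bounds."""

    unique_id = "?"
    tracks: Dict[str, object] = {}
    _any_length = True

    def __len__(self):  # pragma: no cover - trivial
        return 10 ** 9


class _PermissiveProteome:
    _protein = _AnyLengthProtein()

    def __contains__(self, unique_id):
        return True

    def protein(self, unique_id):
        return self._protein


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_attributes(attributes: Dict[str, str]) -> List[str]:
    out = []
    for key, value in attributes.items():
        if ":" in key or "\t" in key or not key:
            raise ValueError(f"attribute key {key!r} must be non-empty, without ':' or tabs")
        if "\t" in str(value):
            raise ValueError(f"attribute value for {key!r} contains a tab")
        out.append(f"{key}:{value}")
    return out


def write_domains(proteome: Proteome, path: str,
                  domain_type: Optional[str] = None) -> int:
    """Write domains (optionally one type only); returns lines written.
    Output order is protein insertion order, then domain insertion order."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for protein in proteome:
            for dom in protein.domains:
                if domain_type is not None and dom.domain_type != domain_type:
                    continue
                fields = [protein.unique_id, str(dom.start), str(dom.stop),
                          dom.domain_type] + _format_attributes(dom.attributes)
                fh.write("\t".join(fields) + "\n")
                n += 1
    return n


def write_sites(proteome: Proteome, path: str,
                site_type: Optional[str] = None) -> int:
    """Write sites (optionally one type only); value serialized with repr
    precision so round trips are exact."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for protein in proteome:
            for site in protein.sites:
                if site_type is not None and site.site_type != site_type:
                    continue
                fields = [protein.unique_id, str(site.position), site.site_type,
                          site.symbol, repr(site.value)] + _format_attributes(site.attributes)
                fh.write("\t".join(fields) + "\n")
                n += 1
    return n


def write_tracks(proteome: Proteome, path: str,
                 mode: str = "values",
                 track_name: Optional[str] = None) -> int:
    """Write all tracks of one kind (optionally one name only). A tracks file
    holds a single kind because the reader parses a whole file in one mode."""
    if mode not in ("values", "symbols"):
        raise ValueError("mode must be 'values' or 'symbols'")
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for protein in proteome:
            for name, track in protein.tracks.items():
                if track.kind != mode:
                    continue
                if track_name is not None and name != track_name:
                    continue
                if mode == "values":
                    tokens = [repr(v) for v in track.values]
                else:
                    tokens = list(track.symbols)
                fh.write("\t".join([protein.unique_id, name] + tokens) + "\n")
                n += 1
    return n


def write_protein_attributes(proteome: Proteome, path: str) -> int:
    """Write one line per protein that has attributes."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for protein in proteome:
            if not protein.attributes:
                continue
            fields = [protein.unique_id] + _format_attributes(protein.attributes)
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n
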