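"""GenBank flat-file input/output with compound (``join``) CDS locations.

This module is the package's only boundary where GenBank's 1-based
inclusive coordinates appear.  :meth:`Location.as_zero_based` is the single
documented adapter to the 0-based half-open convention used by every
downstream module.

Biopython (``Bio.SeqIO``) does the actual flat-file parsing and rendering;
this module normalises its output into small typed records carrying exactly
what frameshift detection needs: CDS features, their (possibly compound)
locations, strand, and the ``/product`` qualifier.
"""

from __future__ import annotations

import io
import logging
import os
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .dna import clean_sequence

log = logging.getLogger(__name__)

__all__ = [
    "Location",
    "CDSFeature",
    "GenomeRecord",
    "GenBankError",
    "read_genbank",
    "write_genbank",
]


class GenBankError(ValueError):
    """Raised for malformed GenBank input or un-serialisable records."""


@dataclass(frozen=True, order=True)
class Location:
    """One contiguous span, GenBank convention: 1-based, inclusive ends."""

    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenBankError(f"invalid location {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise GenBankError(f"invalid strand {self.strand!r}")

    def as_zero_based(self) -> tuple[int, int]:
        """The single 1-based -> 0-based half-open conversion point."""
        return self.start - 1, self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CDSFeature:
    """A coding-sequence feature; ``locations`` are in biological 5'->3' order."""

    locations: list[Location]
    product: str = ""

    def __post_init__(self) -> None:
        if not self.locations:
            raise GenBankError("CDS feature needs at least one location")
        strands = {loc.strand for loc in self.locations}
        if len(strands) != 1:
            raise GenBankError("all locations of a CDS must share one strand")

    @property
    def strand(self) -> int:
        return self.locations[0].strand

    @property
    def is_joined(self) -> bool:
        return len(self.locations) > 1

    @property
    def span(self) -> tuple[int, int]:
        """Overall 1-based inclusive extent (min start, max end)."""
        return (min(l.start for l in self.locations),
                max(l.end for l in self.locations))


@dataclass
class GenomeRecord:
    name: str
    sequence: str
    circular: bool = False
    features: list[CDSFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenBankError(f"record {self.name!r} has an empty sequence")
        n = len(self.sequence)
        for feat in self.features:
            for loc in feat.locations:
                if loc.end > n:
                    raise GenBankError(
                        f"record {self.name!r}: location {loc.start}..{loc.end} "
                        f"exceeds sequence length {n}")


def _biological_order(locs: list[Location]) -> list[Location]:
    ordered = sorted(locs, key=lambda l: l.start)
    if locs and locs[0].strand == -1:
        ordered.reverse()
    return ordered


def _convert_feature(feat: SeqFeature, name: str) -> CDSFeature:
    loc = feat.location
    if loc is None:
        raise GenBankError(
            f"record {name!r}: could not parse coordinates of a CDS feature "
            f"(malformed location line)")
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    locations = []
    for part in parts:
        strand = part.strand if part.strand in (1, -1) else 1
        locations.append(Location(int(part.start) + 1, int(part.end), strand))
    product = feat.qualifiers.get("product", [""])[0]
    return CDSFeature(locations=_biological_order(locations), product=product)


def _parse_or_raise(handle):
    """Iterate SeqIO records, converting parser failures to GenBankError."""
    parser = SeqIO.parse(handle, "genbank")
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:   # malformed coordinates, truncated ORIGIN, ...
            raise GenBankError(f"could not parse GenBank input: {exc}") from exc
        yield rec


def read_genbank(source: str | os.PathLike) -> list[GenomeRecord]:
    """Parse GenBank flat-file text (or a path to one) into GenomeRecords.

    Multi-record files yield one record per LOCUS block.  Only CDS features
    are kept; other feature types are skipped (logged at debug level).
    Sequences are uppercased, U mapped to T, and ambiguity codes collapsed
    to N.  Raises :class:`GenBankError` on malformed coordinates or a
    missing ORIGIN sequence.
    """
    if isinstance(source, str) and ("\n" in source or source.lstrip().startswith("LOCUS")):
        handle: io.TextIOBase = io.StringIO(source)
    else:
        handle = open(os.fspath(source))
    records = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Biopython warns on odd LOCUS lines
            for rec in _parse_or_raise(handle):
                try:
                    seq = str(rec.seq)
                except Exception:
                    seq = ""
                if not seq:
                    raise GenBankError(
                        f"record {rec.name!r} has no ORIGIN sequence")
                features = []
                for feat in rec.features:
                    if feat.type != "CDS":
                        log.debug("skipping %s feature in %s", feat.type, rec.name)
                        continue
                    features.append(_convert_feature(feat, rec.name))
                records.append(GenomeRecord(
                    name=rec.name,
                    sequence=clean_sequence(seq),
                    circular=rec.annotations.get("topology", "") == "circular",
                    features=features,
                ))
    finally:
        handle.close()
    return records


def _render_location(feat: CDSFeature):
    parts = []
    # GenBank serialises join(...) parts in ascending coordinate order on
    # both strands; biological order is restored on read.
    for loc in sorted(feat.locations, key=lambda l: l.start):
        s0, e0 = loc.as_zero_based()
        parts.append(SimpleLocation(s0, e0, strand=loc.strand))
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def write_genbank(records: list[GenomeRecord]) -> str:
    """Render GenomeRecords as GenBank flat-file text.

    Joined features are serialised with the ``join`` keyword; coordinates
    are 1-based inclusive.  Out-of-bounds locations raise before any output
    is produced.
    """
    seqrecords = []
    for rec in records:
        GenomeRecord(rec.name, rec.sequence, rec.circular, rec.features)  # re-validate
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.name,
            name=rec.name,
            description="",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.circular else "linear",
            },
        )
        for feat in rec.features:
            qualifiers = {"product": [feat.product]} if feat.product else {}
            sr.features.append(
                SeqFeature(_render_location(feat), type="CDS", qualifiers=qualifiers))
        seqrecords.append(sr)
    out = io.StringIO()
    SeqIO.write(seqrecords, out, "genbank")
    return out.getvalue()
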