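"""Readers and writers for the file dialects the pipeline touches.

Two hit-table dialects are supported: the HMMER3 per-domain tabular
format written by ``hmmsearch --domtblout`` (whitespace-separated,
``#``-prefixed comments) and an internal TSV that mirrors just the
columns this analysis needs, so synthetic and real data share one
in-memory representation. All coordinates are 1-based inclusive; the
per-domain E-value is the *independent* E-value column, the score that
is comparable across searches.

Readers parse line-wise so that malformed or invariant-violating rows
can be reported with their line number. Writers emit TSV with a header
line.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .model import (
    FEATURE_KINDS,
    ClanMap,
    DomainHit,
    FamilyCalibration,
    FeatureTrack,
    SeedRegion,
)

HIT_COLUMNS = (
    "seq_id",
    "family_acc",
    "seq_evalue",
    "dom_evalue",
    "bit_score",
    "bias_score",
    "ali_start",
    "ali_end",
    "env_start",
    "env_end",
)

# 0-based field indices in the hmmsearch --domtblout dialect
_DOMTBL_MIN_FIELDS = 22
_DOMTBL = {
    "target_name": 0,
    "query_name": 3,
    "query_acc": 4,
    "seq_evalue": 6,
    "dom_evalue": 12,  # independent E-value (i-Evalue)
    "bit_score": 13,
    "bias_score": 14,
    "ali_start": 17,
    "ali_end": 18,
    "env_start": 19,
    "env_end": 20,
}


def _data_lines(path: str | os.PathLike):
    """Yield (1-based line number, stripped text) for non-comment, non-blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _build_hit(fields: dict[str, str], lineno: int) -> DomainHit:
    try:
        return DomainHit(
            seq_id=fields["seq_id"],
            family_acc=fields["family_acc"],
            seq_evalue=float(fields["seq_evalue"]),
            dom_evalue=float(fields["dom_evalue"]),
            bit_score=float(fields["bit_score"]),
            bias_score=float(fields["bias_score"]),
            ali_start=int(fields["ali_start"]),
            ali_end=int(fields["ali_end"]),
            env_start=int(fields["env_start"]),
            env_end=int(fields["env_end"]),
        )
    except ValidationError as exc:
        raise ValidationError(str(exc), line=lineno) from exc
    except (ValueError, KeyError) as exc:
        raise ParseError(f"malformed hit row: {exc}", line=lineno) from exc


def read_domain_hits(path: str | os.PathLike, dialect: str = "auto") -> list[DomainHit]:
    """Read a per-domain hit table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"domtbl"`` for the HMMER3 per-domain tabular format,
        ``"tsv"`` for the internal tab-separated dialect, or ``"auto"``
        to decide from the first data line (the internal dialect starts
        with a ``seq_id`` header).
    """
    if dialect not in ("auto", "domtbl", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "auto":
        dialect = "tsv"
        for _, line in _data_lines(path):
            if not line.startswith("seq_id\t"):
                dialect = "domtbl"
            break
    if dialect == "domtbl":
        return _read_domtbl(path)
    return _read_hits_tsv(path)


def _read_domtbl(path: str | os.PathLike) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) < _DOMTBL_MIN_FIELDS:
            raise ParseError(
                f"expected >= {_DOMTBL_MIN_FIELDS} whitespace-separated fields, "
                f"got {len(cols)}",
                line=lineno,
            )
        family = cols[_DOMTBL["query_acc"]]
        if family == "-":  # accession column may be absent; fall back to name
            family = cols[_DOMTBL["query_name"]]
        fields = {"seq_id": cols[_DOMTBL["target_name"]], "family_acc": family}
        for key in (
            "seq_evalue",
            "dom_evalue",
            "bit_score",
            "bias_score",
            "ali_start",
            "ali_end",
            "env_start",
            "env_end",
        ):
            fields[key] = cols[_DOMTBL[key]]
        hits.append(_build_hit(fields, lineno))
    return hits


def _read_hits_tsv(path: str | os.PathLike) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "seq_id":  # header
            if tuple(cols) != HIT_COLUMNS:
                raise ParseError(
                    f"unexpected header columns {cols!r}", line=lineno
                )
            continue
        if len(cols) != len(HIT_COLUMNS):
            raise ParseError(
                f"expected {len(HIT_COLUMNS)} tab-separated fields, got {len(cols)}",
                line=lineno,
            )
        hits.append(_build_hit(dict(zip(HIT_COLUMNS, cols)), lineno))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    """Write hits to the internal TSV dialect (round-trips exactly)."""
    rows = [
        (
            h.seq_id,
            h.family_acc,
            f"{h.seq_evalue:.6e}",
            f"{h.dom_evalue:.6e}",
            f"{h.bit_score:.2f}",
            f"{h.bias_score:.2f}",
            h.ali_start,
            h.ali_end,
            h.env_start,
            h.env_end,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clan_map(path: str | os.PathLike) -> ClanMap:
    """Read a family→clan TSV (first two columns: family accession, clan
    accession; the clan field may be empty; extra columns are ignored).

    A family listed twice with conflicting clans is an error.
    """
    entries: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "family_acc":  # header
            continue
        if len(cols) < 1 or not cols[0]:
            raise ParseError("missing family accession", line=lineno)
        family = cols[0]
        clan = cols[1] if len(cols) > 1 else ""
        if family in entries and entries[family] != clan:
            raise ValidationError(
                f"family {family} mapped to conflicting clans "
                f"{entries[family]!r} and {clan!r}",
                line=lineno,
            )
        entries[family] = clan
    return ClanMap(entries={f: c for f, c in entries.items() if c})


def write_clan_map(clans: ClanMap, path: str | os.PathLike, families: Sequence[str] | None = None) -> None:
    """Write a family→clan TSV. ``families`` may list clanless families to
    include with an empty clan field."""
    fams = sorted(set(clans.entries) | set(families or ()))
    rows = [(f, clans.entries.get(f, "")) for f in fams]
    pd.DataFrame(rows, columns=["family_acc", "clan_acc"]).to_csv(path, sep="\t", index=False)


def read_feature_tracks(path: str | os.PathLike) -> list[FeatureTrack]:
    """Read a BED-like TSV of predictor segments: seq_id, start, end, kind.

    Coordinates are 1-based inclusive (declared in the file header).
    Segments of the same (sequence, kind) are normalized: sorted and
    merged where overlapping or adjacent.
    """
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "seq_id":  # header
            continue
        if len(cols) != 4:
            raise ParseError(f"expected 4 fields, got {len(cols)}", line=lineno)
        seq_id, start_s, end_s, kind = cols
        if kind not in FEATURE_KINDS:
            raise ParseError(f"unknown feature kind {kind!r}", line=lineno)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates: {exc}", line=lineno) from exc
        if start > end:
            raise ValidationError(f"segment {start}-{end} has start > end", line=lineno)
        raw.setdefault((seq_id, kind), []).append((start, end))
    return [
        FeatureTrack(seq_id, kind, tuple(segs)).normalized()
        for (seq_id, kind), segs in sorted(raw.items())
    ]


def write_feature_tracks(tracks: Iterable[FeatureTrack], path: str | os.PathLike) -> None:
    rows = [
        (t.seq_id, s, e, t.kind)
        for t in tracks
        for (s, e) in t.segments
    ]
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        pd.DataFrame(rows, columns=["seq_id", "start", "end", "kind"]).to_csv(
            fh, sep="\t", index=False
        )


def read_seed_regions(path: str | os.PathLike) -> list[SeedRegion]:
    """Read seed-member regions: family_acc, seq_id, start, end (1-based inclusive)."""
    regions: list[SeedRegion] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "family_acc":
            continue
        if len(cols) != 4:
            raise ParseError(f"expected 4 fields, got {len(cols)}", line=lineno)
        try:
            region = SeedRegion(cols[0], cols[1], int(cols[2]), int(cols[3]))
        except ValidationError as exc:
            raise ValidationError(str(exc), line=lineno) from exc
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates: {exc}", line=lineno) from exc
        regions.append(region)
    return regions


def write_seed_regions(regions: Iterable[SeedRegion], path: str | os.PathLike) -> None:
    rows = [(r.family_acc, r.seq_id, r.start, r.end) for r in regions]
    pd.DataFrame(rows, columns=["family_acc", "seq_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_family_calibrations(path: str | os.PathLike) -> list[FamilyCalibration]:
    """Read per-family calibration rows: family_acc, ga_bits, lam, tau, db_size."""
    out: list[FamilyCalibration] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "family_acc":
            continue
        if len(cols) != 5:
            raise ParseError(f"expected 5 fields, got {len(cols)}", line=lineno)
        try:
            out.append(
                FamilyCalibration(
                    cols[0], float(cols[1]), float(cols[2]), float(cols[3]), int(cols[4])
                )
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), line=lineno) from exc
        except ValueError as exc:
            raise ParseError(f"malformed calibration row: {exc}", line=lineno) from exc
    return out


def write_family_calibrations(
    calibs: Iterable[FamilyCalibration], path: str | os.PathLike
) -> None:
    rows = [(c.family_acc, c.ga_bits, c.lam, c.tau, c.db_size) for c in calibs]
    pd.DataFrame(rows, columns=["family_acc", "ga_bits", "lam", "tau", "db_size"]).to_csv(
        path, sep="\t", index=False
    )
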