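"""Death-certificate records: reading, validation, and cause extraction.

A WHO-style medical certificate of cause of death has two sections: Part I
carries the causal pathway (one or more ICD-10 codes per line, the
underlying cause usually on the last line) and Part II carries other
contributing conditions.  Records arrive in one of two tabular dialects:

* **entity axis** — one CSV row per code mention, preserving part, line and
  within-line position exactly as written on the certificate;
* **record axis** — one CSV row per death, the underlying cause first,
  followed by the remaining causes with positional information lost.

From each certificate we extract one underlying-cause category (UCoD) and a
set of contributing-cause categories (CCoDs): Part I codes strictly after
the UCoD in reading order, plus all Part II codes.  Part I codes above or
left of the UCoD are consequences of it and are ignored.  Causes are
deduplicated at category level and a category equal to the UCoD's is never
also a CCoD.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .mapping import CategoryMapping, InvalidCodeError, normalize_code

__all__ = [
    "Certificate",
    "ResolvedRecord",
    "CertificateError",
    "DEFAULT_AGE_BREAKS",
    "read_certificates",
    "write_certificates",
    "resolve_record",
    "resolve_records",
    "age_group_label",
]

logger = logging.getLogger(__name__)

#: Default age-group boundaries (years): 60-74, 75-84, 85+.
DEFAULT_AGE_BREAKS: tuple[int, ...] = (60, 75, 85)

Dialect = Literal["entity_axis", "record_axis"]


class CertificateError(ValueError):
    """Raised for malformed certificate input."""


@dataclass
class Certificate:
    """One death record as certified.

    ``part1`` is an ordered list of lines, each an ordered list of
    normalised ICD-10 codes.  ``ucod_position`` locates the underlying
    cause within Part I as 0-based ``(line, position)``; it is ``None`` for
    record-axis input, where position on the certificate is unknown and the
    non-first causes are stored in ``part2``.
    """

    id: str
    ucod: str
    part1: list[list[str]] = field(default_factory=list)
    part2: list[str] = field(default_factory=list)
    ucod_position: tuple[int, int] | None = None
    sex: str | None = None
    age_years: int | None = None

    def __post_init__(self) -> None:
        self.ucod = normalize_code(self.ucod)
        self.part1 = [[normalize_code(c) for c in line] for line in self.part1]
        self.part2 = [normalize_code(c) for c in self.part2]
        if self.ucod_position is not None:
            line, pos = self.ucod_position
            try:
                placed = self.part1[line][pos]
            except IndexError:
                raise CertificateError(
                    f"certificate {self.id!r}: ucod_position {self.ucod_position} "
                    "outside Part I"
                ) from None
            if placed != self.ucod:
                raise CertificateError(
                    f"certificate {self.id!r}: code at ucod_position is {placed}, "
                    f"not the stated UCoD {self.ucod}"
                )
        if self.age_years is not None and self.age_years < 0:
            raise CertificateError(f"certificate {self.id!r}: negative age")


@dataclass(frozen=True)
class ResolvedRecord:
    """Per-death analysis unit: UCoD category, CCoD category set, strata."""

    id: str
    ucod_cat: str
    ccod_cats: frozenset[str]
    strata: dict[str, str] = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.ucod_cat in self.ccod_cats:
            raise CertificateError(
                f"record {self.id!r}: UCoD category also present among CCoDs"
            )

    @property
    def n_ccod(self) -> int:
        return len(self.ccod_cats)

    def stratum_key(self, axes: Sequence[str]) -> tuple[str, ...]:
        return tuple(self.strata.get(a, "") for a in axes)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_ENTITY_COLUMNS = ["id", "sex", "age", "part", "line", "position", "icd10", "is_ucod"]


def _parse_optional_sex(value: str) -> str | None:
    value = value.strip()
    return value or None


def _parse_optional_age(value: str, where: str) -> int | None:
    value = value.strip()
    if not value:
        return None
    try:
        age = int(value)
    except ValueError:
        raise CertificateError(f"{where}: age {value!r} is not an integer") from None
    return age


def read_certificates(path: str | Path, dialect: Dialect) -> list[Certificate]:
    """Read certificates from CSV in the given dialect.

    Entity-axis files have columns ``id,sex,age,part,line,position,icd10,
    is_ucod`` with one row per code mention; record-axis files have
    ``id,sex,age,cause_1,...,cause_k`` with the UCoD in ``cause_1``.
    Comment lines starting with ``#`` are skipped.  Raises
    :class:`CertificateError` naming the offending row on malformed codes,
    duplicate positions, or a missing underlying cause.
    """
    if dialect == "entity_axis":
        return _read_entity(Path(path))
    if dialect == "record_axis":
        return _read_record(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_entity(path: Path) -> list[Certificate]:
    certs: list[Certificate] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _ENTITY_COLUMNS:
            raise CertificateError(
                f"{path}: entity-axis file must have columns {','.join(_ENTITY_COLUMNS)}"
            )
        # accumulate per id in order of first appearance
        order: list[str] = []
        rows_by_id: dict[str, list[tuple[int, dict]]] = {}
        for lineno, row in enumerate(reader, start=2):
            cid = row["id"].strip()
            if not cid:
                raise CertificateError(f"{path} row {lineno}: empty id")
            if cid not in rows_by_id:
                rows_by_id[cid] = []
                order.append(cid)
            rows_by_id[cid].append((lineno, row))

    for cid in order:
        seen_pos: set[tuple[int, int, int]] = set()
        part1: dict[int, dict[int, str]] = {}
        part2: dict[int, str] = {}
        ucod_at: tuple[int, int] | None = None
        sex = None
        age = None
        for lineno, row in rows_by_id[cid]:
            where = f"{path} row {lineno}"
            sex = sex or _parse_optional_sex(row["sex"])
            if age is None:
                age = _parse_optional_age(row["age"], where)
            try:
                part = int(row["part"])
                line = int(row["line"])
                pos = int(row["position"])
            except (TypeError, ValueError):
                raise CertificateError(f"{where}: part/line/position must be integers") from None
            if part not in (1, 2) or line < 1 or pos < 1:
                raise CertificateError(f"{where}: bad part/line/position")
            key = (part, line, pos)
            if key in seen_pos:
                raise CertificateError(
                    f"{where}: duplicate position part={part} line={line} position={pos} "
                    f"for certificate {cid!r}"
                )
            seen_pos.add(key)
            try:
                code = normalize_code(row["icd10"])
            except InvalidCodeError as exc:
                raise CertificateError(f"{where}: {exc}") from None
            is_ucod = row["is_ucod"].strip() == "1"
            if part == 1:
                part1.setdefault(line, {})[pos] = code
                if is_ucod:
                    if ucod_at is not None:
                        raise CertificateError(
                            f"{where}: certificate {cid!r} flags more than one UCoD"
                        )
                    ucod_at = (line, pos)
            else:
                if is_ucod:
                    raise CertificateError(
                        f"{where}: UCoD flagged in Part II; the underlying cause "
                        "must lie on a Part I line"
                    )
                part2[(line - 1) * 100 + pos] = code
        if ucod_at is None:
            raise CertificateError(f"{path}: certificate {cid!r} has no UCoD flagged")

        lines_sorted = sorted(part1)
        line_index = {ln: i for i, ln in enumerate(lines_sorted)}
        p1 = []
        pos_index: dict[tuple[int, int], tuple[int, int]] = {}
        for ln in lines_sorted:
            positions = sorted(part1[ln])
            pos_index.update({(ln, p): (line_index[ln], j) for j, p in enumerate(positions)})
            p1.append([part1[ln][p] for p in positions])
        ucod_line, ucod_pos = pos_index[ucod_at]
        certs.append(
            Certificate(
                id=cid,
                ucod=p1[ucod_line][ucod_pos],
                part1=p1,
                part2=[part2[k] for k in sorted(part2)],
                ucod_position=(ucod_line, ucod_pos),
                sex=sex,
                age_years=age,
            )
        )
    return certs


def _read_record(path: Path) -> list[Certificate]:
    certs: list[Certificate] = []
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(line for line in fh if not line.startswith("#"))
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != ["id", "sex", "age"] or not (
            len(header) > 3 and header[3].strip() == "cause_1"
        ):
            raise CertificateError(
                f"{path}: record-axis file must have columns id,sex,age,cause_1,..."
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(c.strip() for c in row):
                continue
            where = f"{path} row {lineno}"
            cid = row[0].strip()
            if not cid:
                raise CertificateError(f"{where}: empty id")
            if cid in seen_ids:
                raise CertificateError(f"{where}: duplicate certificate id {cid!r}")
            seen_ids.add(cid)
            causes = [c.strip() for c in row[3:] if c.strip()]
            if not causes:
                raise CertificateError(f"{where}: no causes listed (missing UCoD)")
            try:
                norm = [normalize_code(c) for c in causes]
            except InvalidCodeError as exc:
                raise CertificateError(f"{where}: {exc}") from None
            certs.append(
                Certificate(
                    id=cid,
                    ucod=norm[0],
                    part1=[],
                    part2=norm[1:],
                    ucod_position=None,
                    sex=_parse_optional_sex(row[1]),
                    age_years=_parse_optional_age(row[2], where),
                )
            )
    return certs


def write_certificates(
    certs: Iterable[Certificate], path: str | Path, dialect: Dialect
) -> None:
    """Write certificates as CSV in the given dialect (normalised form).

    Writing then re-reading is lossless for the fields the dialect can
    carry; a certificate without Part I positions is written with its UCoD
    as a single first Part I line in the entity dialect.
    """
    certs = list(certs)
    path = Path(path)
    if dialect == "entity_axis":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_ENTITY_COLUMNS)
            for cert in certs:
                sex = cert.sex or ""
                age = "" if cert.age_years is None else cert.age_years
                part1 = cert.part1
                upos = cert.ucod_position
                if upos is None:
                    part1 = [[cert.ucod]] + part1
                    upos = (0, 0)
                for i, line in enumerate(part1):
                    for j, code in enumerate(line):
                        writer.writerow(
                            [cert.id, sex, age, 1, i + 1, j + 1, code,
                             1 if (i, j) == upos else 0]
                        )
                for j, code in enumerate(cert.part2):
                    writer.writerow([cert.id, sex, age, 2, 1, j + 1, code, 0])
    elif dialect == "record_axis":
        width = max((len(_flat_non_ucod(c)) for c in certs), default=0)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "sex", "age"] + [f"cause_{k}" for k in range(1, width + 2)]
            )
            for cert in certs:
                others = _flat_non_ucod(cert)
                row = [cert.id, cert.sex or "",
                       "" if cert.age_years is None else cert.age_years,
                       cert.ucod] + others + [""] * (width - len(others))
                writer.writerow(row)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _flat_non_ucod(cert: Certificate) -> list[str]:
    """All causes except the UCoD occurrence itself, in reading order."""
    codes: list[str] = []
    for i, line in enumerate(cert.part1):
        for j, code in enumerate(line):
            if cert.ucod_position is not None and (i, j) == cert.ucod_position:
                continue
            codes.append(code)
    codes.extend(cert.part2)
    return codes


# ---------------------------------------------------------------------------
# Resolution: certificate -> (UCoD category, CCoD category set, strata)
# ---------------------------------------------------------------------------


def age_group_label(age: int, breaks: Sequence[int]) -> str | None:
    """Age-group label for *age* given ascending break points.

    Breaks ``(60, 75, 85)`` yield groups ``"60-74"``, ``"75-84"``,
    ``"85+"``.  Ages below the first break belong to no group (``None``).
    """
    breaks = sorted(breaks)
    if age < breaks[0]:
        return None
    for lo, hi in zip(breaks, breaks[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi - 1}"
    return f"{breaks[-1]}+"


def _ccod_candidates(cert: Certificate, part2_only: bool) -> list[str]:
    if part2_only:
        return list(cert.part2)
    if cert.ucod_position is None:
        # record axis: position lost, every non-first cause is a candidate
        return _flat_non_ucod(cert)
    li, pi = cert.ucod_position
    candidates = list(cert.part1[li][pi + 1:])
    for line in cert.part1[li + 1:]:
        candidates.extend(line)
    candidates.extend(cert.part2)
    return candidates


def resolve_record(
    cert: Certificate,
    mapping: CategoryMapping,
    age_breaks: Sequence[int] = DEFAULT_AGE_BREAKS,
    lenient: bool = False,
    part2_only: bool = False,
) -> ResolvedRecord:
    """Map a certificate to its per-death analysis unit.

    CCoD candidates are the Part I codes strictly after the UCoD in reading
    order (right of it on the same line, then all later lines) plus every
    Part II code; for record-axis input, all non-first causes.  Candidates
    are mapped to categories, deduplicated, and the UCoD's own category is
    dropped.  ``part2_only`` restricts candidates to Part II, replicating
    the narrower convention used by earlier arbitrary-weight analyses.
    """
    ucod_cat = mapping.map_code(cert.ucod, lenient=lenient)
    cats = {mapping.map_code(c, lenient=lenient) for c in _ccod_candidates(cert, part2_only)}
    cats.discard(ucod_cat)
    strata: dict[str, str] = {}
    if cert.sex is not None:
        strata["sex"] = cert.sex
    if cert.age_years is not None:
        label = age_group_label(cert.age_years, age_breaks)
        if label is not None:
            strata["age_group"] = label
    return ResolvedRecord(cert.id, ucod_cat, frozenset(cats), strata)


def resolve_records(
    certs: Iterable[Certificate],
    mapping: CategoryMapping,
    age_breaks: Sequence[int] = DEFAULT_AGE_BREAKS,
    lenient: bool = False,
    part2_only: bool = False,
) -> list[ResolvedRecord]:
    """Resolve many certificates, excluding deaths below the first age break.

    Certificates whose age is known and below ``min(age_breaks)`` fall
    outside the study population and are dropped with a logged count.
    """
    breaks = sorted(age_breaks)
    out: list[ResolvedRecord] = []
    excluded = 0
    for cert in certs:
        if cert.age_years is not None and cert.age_years < breaks[0]:
            excluded += 1
            continue
        out.append(resolve_record(cert, mapping, breaks, lenient, part2_only))
    if excluded:
        logger.info("excluded %d certificates below age %d", excluded, breaks[0])
    return out
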