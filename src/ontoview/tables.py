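"""ASCT+B-style table parsing, candidate extraction and table generation.

ASCT+B tables record hierarchies of anatomical structures (AS), cell types
(CT) and biomarkers (B) in column groups ``AS/1``, ``AS/2``, ..., ``CT/1``,
..., each with optional ``/LABEL`` (ontology label) and ``/ID`` columns; the
bare ``ROLE/n`` column holds the author's own label.  Relationships are
encoded by adjacency within a row: adjacent terms form an object (left) /
subject (right) duple — e.g. a row ``kidney | nephron | renal corpuscle``
records that the renal corpuscle stands in some hierarchical relationship to
the nephron and the nephron to the kidney.

Candidate extraction turns those duples into typed candidates (AS-AS, CT-AS,
CT-CT) for the validator; :func:`view_to_table` performs the reverse mapping
from an ontology view to a nested table for expert review.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional

from .model import SUBCLASS, Curie, Predicate

if TYPE_CHECKING:  # pragma: no cover
    from .validate import ValidationProfile
    from .views import ViewGraph

logger = logging.getLogger("ontoview")

_HEADER_RE = re.compile(r"^([A-Za-z]+)/(\d+)(?:/(LABEL|ID))?$")

AS_AS = "AS_AS"
CT_AS = "CT_AS"
CT_CT = "CT_CT"


@dataclass
class TableDialect:
    """CSV dialect settings for a table source.

    ``header_row`` is the 0-based index of the header row; None auto-detects
    the first row containing an ``AS/1``-style column (official exports carry
    ~10 metadata banner rows above it).  ``vasculature`` selects
    ccf_branching_part_of instead of ccf_part_of for AS-AS duples, per the
    authoring SOP's organ-vs-vasculature distinction.
    """

    header_row: Optional[int] = None
    as_role: str = "AS"
    ct_role: str = "CT"
    b_role_prefix: str = "B"
    vasculature: bool = False


@dataclass
class TableCell:
    role: str                       # AS | CT | B
    level: int                      # 1-based column-group index
    id: Optional[Curie] = None
    ontology_label: Optional[str] = None
    user_label: Optional[str] = None
    row: int = 0                    # 0-based data-row index
    biomarker_type: Optional[str] = None
    unmapped: bool = False          # has a label but no usable id
    invalid_id: bool = False

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError(f"cell level must be >= 1, got {self.level}")

    @property
    def best_label(self) -> str:
        return self.ontology_label or self.user_label or (str(self.id) if self.id else "")


@dataclass
class TableDocument:
    rows: list[list[TableCell]] = field(default_factory=list)
    provenance: str = ""
    dialect: TableDialect = field(default_factory=TableDialect)

    def term_ids(self) -> set[Curie]:
        return {c.id for row in self.rows for c in row if c.id is not None}

    def labels(self) -> dict[Curie, str]:
        out: dict[Curie, str] = {}
        for row in self.rows:
            for c in row:
                if c.id is not None and c.id not in out and c.best_label:
                    out[c.id] = c.best_label
        return out


@dataclass(frozen=True)
class CandidateTriple:
    """One table-derived duple: subject = right-hand cell, object = left."""

    subject: TableCell
    object: TableCell
    pair_kind: str                  # AS_AS | CT_AS | CT_CT
    declared_relation: str          # CCF annotation-relation token
    provenance: tuple[int, str] = (0, "")   # (row, column-pair description)


@dataclass
class ExtractionReport:
    candidates: list[CandidateTriple] = field(default_factory=list)
    skipped_cells: list[TableCell] = field(default_factory=list)
    biomarker_records: list[tuple[TableCell, TableCell]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_table(
    source: str,
    dialect: Optional[TableDialect] = None,
    provenance: str = "table",
) -> TableDocument:
    """Parse ASCT+B-style CSV text into a :class:`TableDocument`.

    Cells with a label but no id are retained and flagged ``unmapped``; a
    malformed CURIE in an ID field flags the cell ``invalid_id`` but keeps
    the row.  Missing header or duplicate column names raise ValueError.
    """
    dialect = dialect or TableDialect()
    reader = list(csv.reader(io.StringIO(source)))
    header_idx = _find_header(reader, dialect)
    header = [h.strip() for h in reader[header_idx]]

    seen: set[str] = set()
    for name in header:
        if name and name in seen:
            raise ValueError(f"duplicate column name in header: {name!r}")
        if name:
            seen.add(name)

    # column index -> (role, level, field, biomarker_type)
    columns: dict[int, tuple[str, int, str, Optional[str]]] = {}
    for i, name in enumerate(header):
        m = _HEADER_RE.match(name)
        if m is None:
            continue
        role_token, level, part = m.group(1), int(m.group(2)), m.group(3)
        role, btype = _normalize_role(role_token, dialect)
        if role is None:
            continue
        kind = {"LABEL": "label", "ID": "id", None: "user"}[part]
        columns[i] = (role, level, kind, btype)

    if not columns:
        raise ValueError("no ASCT+B column groups found in header")

    doc = TableDocument(provenance=provenance, dialect=dialect)
    for row_i, raw in enumerate(reader[header_idx + 1 :]):
        cells: dict[tuple[str, int], TableCell] = {}
        order: list[tuple[str, int]] = []
        for i, value in enumerate(raw):
            if i not in columns:
                continue
            value = value.strip()
            if not value:
                continue
            role, level, kind, btype = columns[i]
            key = (role, level)
            if key not in cells:
                cells[key] = TableCell(
                    role=role, level=level, row=row_i, biomarker_type=btype
                )
                order.append(key)
            cell = cells[key]
            if kind == "user":
                cell.user_label = value
            elif kind == "label":
                cell.ontology_label = value
            else:
                try:
                    cell.id = Curie.parse(value)
                except ValueError:
                    cell.invalid_id = True
                    logger.warning(
                        "row %d: malformed CURIE %r in %s/%d/ID", row_i, value, role, level
                    )
        row_cells = [cells[k] for k in order]
        for cell in row_cells:
            if cell.id is None:
                cell.unmapped = True
        if row_cells:
            _check_row_order(row_cells, row_i)
            doc.rows.append(row_cells)
    return doc


def _find_header(rows: list[list[str]], dialect: TableDialect) -> int:
    if dialect.header_row is not None:
        if dialect.header_row >= len(rows):
            raise ValueError(f"header row {dialect.header_row} beyond end of file")
        return dialect.header_row
    probe = re.compile(rf"^{re.escape(dialect.as_role)}/\d+(/(LABEL|ID))?$")
    for i, row in enumerate(rows):
        if any(probe.match(c.strip()) for c in row):
            return i
    raise ValueError("no header row containing an AS/1 column group found")


def _normalize_role(
    token: str, dialect: TableDialect
) -> tuple[Optional[str], Optional[str]]:
    """Map a header role token to (role, biomarker_type)."""
    if token == dialect.as_role:
        return "AS", None
    if token == dialect.ct_role:
        return "CT", None
    if token.startswith(dialect.b_role_prefix):
        rest = token[len(dialect.b_role_prefix) :] or None
        return "B", rest
    return None, None


def _check_row_order(cells: list[TableCell], row_i: int) -> None:
    """Within a row AS levels strictly increase, then CT, then B groups."""
    rank = {"AS": 0, "CT": 1, "B": 2}
    names = {0: "AS", 1: "CT", 2: "B"}
    last_rank, last_level = -1, 0
    for c in cells:
        r = rank[c.role]
        if r < last_rank:
            raise ValueError(
                f"row {row_i}: {c.role} group after {names[last_rank]} groups"
            )
        if r != last_rank:
            last_rank, last_level = r, 0
        if c.role in ("AS", "CT") and c.level <= last_level:
            raise ValueError(
                f"row {row_i}: {c.role} levels not strictly increasing at level {c.level}"
            )
        last_level = c.level


# ---------------------------------------------------------------------------
# Candidate extraction
# ---------------------------------------------------------------------------

def extract_candidates_report(
    doc: TableDocument, profile: "ValidationProfile"
) -> ExtractionReport:
    """Adjacency-convention candidate extraction with a full account.

    Per row: every adjacent (AS_n, AS_m) pair of present AS cells yields an
    AS-AS candidate (subject = right); the deepest AS cell pairs with the
    first CT cell (CT-AS, subject = CT); adjacent CT pairs yield CT-CT.
    Duplicates (same subject id, object id, pair_kind) are removed across
    rows, first occurrence kept.  Cells without ids yield no candidates but
    are accounted for in ``skipped_cells``; B cells yield passthrough
    (CT, B) records only.
    """
    report = ExtractionReport()
    seen: set[tuple[Curie, Curie, str]] = set()

    def emit(subject: TableCell, obj: TableCell, kind: str, row_i: int, col: str) -> None:
        if subject.id is None or obj.id is None:
            for c in (subject, obj):
                if c.id is None and c not in report.skipped_cells:
                    report.skipped_cells.append(c)
            return
        key = (subject.id, obj.id, kind)
        if key in seen:
            return
        seen.add(key)
        relation = profile.ccf_relation(kind, vasculature=doc.dialect.vasculature)
        report.candidates.append(
            CandidateTriple(subject, obj, kind, relation, (row_i, col))
        )

    for row_i, row in enumerate(doc.rows):
        as_cells = [c for c in row if c.role == "AS"]
        ct_cells = [c for c in row if c.role == "CT"]
        b_cells = [c for c in row if c.role == "B"]
        for left, right in zip(as_cells, as_cells[1:]):
            emit(right, left, AS_AS, row_i, f"AS/{left.level}~AS/{right.level}")
        if as_cells and ct_cells:
            deepest_as, first_ct = as_cells[-1], ct_cells[0]
            emit(first_ct, deepest_as, CT_AS, row_i,
                 f"AS/{deepest_as.level}~CT/{first_ct.level}")
        for left, right in zip(ct_cells, ct_cells[1:]):
            emit(right, left, CT_CT, row_i, f"CT/{left.level}~CT/{right.level}")
        if ct_cells:
            for b in b_cells:
                report.biomarker_records.append((ct_cells[-1], b))
    return report


def extract_candidates(
    doc: TableDocument, profile: "ValidationProfile"
) -> list[CandidateTriple]:
    return extract_candidates_report(doc, profile).candidates


# ---------------------------------------------------------------------------
# View -> table
# ---------------------------------------------------------------------------

def view_to_table(
    view: "ViewGraph",
    relation_for_nesting: Curie,
    labels: Optional[Mapping[Curie, str]] = None,
) -> TableDocument:
    """Render a view as a nested AS table, one row per root-to-leaf path.

    Nesting edges are the view edges whose predicate is
    ``relation_for_nesting`` or SubClassOf, oriented part/child (subject) ->
    whole/parent (object).  Roots (no outgoing nesting edge) occupy level 1.
    A term with k parents appears in k rows (duplication, not loss); terms
    with no nesting edge at all become single-cell rows.  Cyclic nesting is
    an error naming a cycle.
    """
    labels = labels or {}
    nesting = [
        (s, o)
        for (s, p, o) in view.edges
        if p == relation_for_nesting or p == SUBCLASS
        if isinstance(s, Curie)
    ]
    nodes = set(view.seed_terms) | {n for e in nesting for n in e}
    children: dict[Curie, list[Curie]] = {}   # parent -> parts
    has_parent: set[Curie] = set()
    for s, o in nesting:
        children.setdefault(o, []).append(s)
        has_parent.add(s)
    for v in children.values():
        v.sort(key=str)

    cycle = _find_cycle(nodes, children)
    if cycle:
        raise ValueError("cyclic nesting graph: " + " -> ".join(map(str, cycle)))

    roots = sorted((n for n in nodes if n not in has_parent), key=str)
    paths: list[list[Curie]] = []

    def walk(node: Curie, path: list[Curie]) -> None:
        path = path + [node]
        kids = children.get(node, [])
        if not kids:
            paths.append(path)
            return
        for kid in kids:
            walk(kid, path)

    for root in roots:
        walk(root, [])

    doc = TableDocument(provenance="view_to_table")
    for row_i, path in enumerate(sorted(paths, key=lambda p: [str(c) for c in p])):
        row = [
            TableCell(
                role="AS",
                level=level,
                id=curie,
                ontology_label=labels.get(curie),
                row=row_i,
            )
            for level, curie in enumerate(path, start=1)
        ]
        doc.rows.append(row)
    return doc


def _find_cycle(
    nodes: set[Curie], children: dict[Curie, list[Curie]]
) -> Optional[list[Curie]]:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}
    parent: dict[Curie, Curie] = {}

    for start in sorted(nodes, key=str):
        if color[start] != WHITE:
            continue
        stack: list[tuple[Curie, int]] = [(start, 0)]
        color[start] = GRAY
        while stack:
            node, i = stack[-1]
            kids = children.get(node, [])
            if i < len(kids):
                stack[-1] = (node, i + 1)
                kid = kids[i]
                if color.get(kid, WHITE) == GRAY:
                    cycle = [kid, node]
                    cur = node
                    while cur != kid and cur in parent:
                        cur = parent[cur]
                        cycle.append(cur)
                    return list(reversed(cycle))
                if color.get(kid, WHITE) == WHITE:
                    color[kid] = GRAY
                    parent[kid] = node
                    stack.append((kid, 0))
            else:
                color[node] = BLACK
                stack.pop()
    return None


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_table_csv(doc: TableDocument) -> str:
    """Emit CSV with ``ROLE/n, ROLE/n/LABEL, ROLE/n/ID`` header groups.

    Groups are sized to the deepest row per role; column order is AS groups,
    CT groups, then B groups; output is byte-identical for identical inputs.
    """
    max_level = {"AS": 0, "CT": 0, "B": 0}
    for row in doc.rows:
        for cell in row:
            max_level[cell.role] = max(max_level[cell.role], cell.level)

    header: list[str] = []
    slots: list[tuple[str, int]] = []
    for role in ("AS", "CT", "B"):
        for level in range(1, max_level[role] + 1):
            header.extend([f"{role}/{level}", f"{role}/{level}/LABEL", f"{role}/{level}/ID"])
            slots.append((role, level))

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    for row in doc.rows:
        by_slot = {(c.role, c.level): c for c in row}
        out: list[str] = []
        for slot in slots:
            cell = by_slot.get(slot)
            if cell is None:
                out.extend(["", "", ""])
            else:
                out.extend([
                    cell.user_label or "",
                    cell.ontology_label or "",
                    str(cell.id) if cell.id else "",
                ])
        writer.writerow(out)
    return buf.getvalue()
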