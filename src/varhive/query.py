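"""SQL queries extended with per-sample genotype conditions.

Sample genotypes live in compressed array blobs, so a stock SQL engine
cannot address one sample's genotype. This module adds the COLUMN.SAMPLE
notation on top of SQLite: in the select list, ``gts.NA12878`` expands to
that sample's genotype string; a ``--gt-filter`` expression such as
``gt_types.mom == HET and gt_types.dad == HET`` is parsed into a boolean
AST and applied to each SQL result row after decompressing its blobs.
The filter therefore never widens the SQL result — it only prunes it.

Grammar (whitespace-insensitive; ``=  =`` is accepted for ``==``)::

    expr  := or
    or    := and ("or" and)*
    and   := unary ("and" unary)*
    unary := "not" unary | "(" expr ")" | cmp
    cmp   := COLUMN "." SAMPLE OP literal
    OP    := "==" | "!=" | "<" | "<=" | ">" | ">="

COLUMN is one of gts, gt_types, gt_phases, gt_depths. Genotype-type
keywords (HOM_REF, HET, HOM_ALT, UNKNOWN) are case-insensitive.

Missing-data semantics: when a sample's genotype is uncalled and the
literal names a called value, ``==`` is false and ``!=`` is true; ordered
comparisons are false. Missing depth is the sentinel -1 and follows plain
numeric semantics, unless ``strict_missing`` makes every comparison on
missing data false.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

from .db import DatabaseHandle
from .gtstore import GT_TYPE_NAMES, UNKNOWN, unpack

__all__ = [
    "Comparison",
    "Not",
    "And",
    "Or",
    "QueryRequest",
    "parse_gt_filter",
    "evaluate_filter",
    "expand_sample_columns",
    "execute_query",
    "GtFilterSyntaxError",
    "UnknownSampleError",
    "same_genotype_for_all",
]

GT_COLUMNS = ("gts", "gt_types", "gt_phases", "gt_depths")
_OPS = ("==", "!=", "<=", ">=", "<", ">")


class GtFilterSyntaxError(ValueError):
    """Malformed genotype-filter expression; message carries the position."""


class UnknownSampleError(KeyError):
    """A COLUMN.SAMPLE token names a sample not in the database."""


@dataclass(frozen=True)
class Comparison:
    column: str
    sample: str
    op: str
    literal: Union[int, float, bool, str]


@dataclass(frozen=True)
class Not:
    child: "Node"


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


Node = Union[Comparison, Not, And, Or]


@dataclass
class QueryRequest:
    sql: str
    gt_filter: Optional[str] = None
    show_header: bool = False
    strict_missing: bool = False


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<op>==|!=|<=|>=|<|>)
      | (?P<str>'[^']*'|"[^"]*")
      | (?P<word>[A-Za-z0-9_.\-/|]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    # tolerate the spaced "=  =" spelling for equality
    text = re.sub(r"(?<![<>!=])=\s*=", "==", text)
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos:].strip() == "":
            break
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise GtFilterSyntaxError(f"cannot tokenize at position {pos}: {text[pos:]!r}")
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


def _coerce_literal(column: str, raw: str, quoted: bool):
    if column == "gt_types":
        if not quoted and raw.upper() in GT_TYPE_NAMES:
            return GT_TYPE_NAMES[raw.upper()]
        try:
            return int(raw)
        except ValueError:
            raise GtFilterSyntaxError(
                f"gt_types literal must be HOM_REF/HET/HOM_ALT/UNKNOWN "
                f"or an integer, got {raw!r}"
            ) from None
    if column == "gt_phases":
        lowered = raw.lower()
        if lowered in ("true", "1"):
            return True
        if lowered in ("false", "0"):
            return False
        raise GtFilterSyntaxError(f"gt_phases literal must be boolean, got {raw!r}")
    if column == "gt_depths":
        try:
            return int(raw)
        except ValueError:
            try:
                return float(raw)
            except ValueError:
                raise GtFilterSyntaxError(
                    f"gt_depths literal must be numeric, got {raw!r}"
                ) from None
    return raw  # gts: genotype string literal


class _Parser:
    def __init__(self, tokens, sample_order: Optional[Sequence[str]]):
        self.tokens = tokens
        self.i = 0
        self.samples = set(sample_order) if sample_order is not None else None

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, -1)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_word(self, word: str) -> bool:
        kind, value, _ = self.peek()
        if kind == "word" and value.lower() == word:
            self.i += 1
            return True
        return False

    def parse(self) -> Node:
        node = self.parse_or()
        if self.i != len(self.tokens):
            _, value, pos = self.peek()
            raise GtFilterSyntaxError(f"unexpected {value!r} at position {pos}")
        return node

    def parse_or(self) -> Node:
        parts = [self.parse_and()]
        while self.expect_word("or"):
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> Node:
        parts = [self.parse_unary()]
        while self.expect_word("and"):
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> Node:
        kind, value, pos = self.peek()
        if kind == "word" and value.lower() == "not":
            self.i += 1
            return Not(self.parse_unary())
        if kind == "lparen":
            self.i += 1
            node = self.parse_or()
            kind, value, pos = self.next()
            if kind != "rparen":
                raise GtFilterSyntaxError(f"expected ')' at position {pos}")
            return node
        return self.parse_cmp()

    def parse_cmp(self) -> Comparison:
        kind, value, pos = self.next()
        if kind != "word" or "." not in value:
            raise GtFilterSyntaxError(
                f"expected COLUMN.SAMPLE at position {pos}, got {value!r}"
            )
        column, _, sample = value.partition(".")
        if column not in GT_COLUMNS:
            raise GtFilterSyntaxError(
                f"unknown column {column!r} at position {pos}; "
                f"valid columns: {', '.join(GT_COLUMNS)}"
            )
        if not sample:
            raise GtFilterSyntaxError(f"missing sample name at position {pos}")
        if self.samples is not None and sample not in self.samples:
            raise UnknownSampleError(f"unknown sample {sample!r}")
        kind, op, pos = self.next()
        if kind != "op":
            raise GtFilterSyntaxError(f"expected comparison operator at position {pos}")
        kind, raw, pos = self.next()
        if kind == "str":
            return Comparison(column, sample, op, _coerce_literal(column, raw[1:-1], True))
        if kind == "word":
            return Comparison(column, sample, op, _coerce_literal(column, raw, False))
        raise GtFilterSyntaxError(f"expected literal at position {pos}")


def parse_gt_filter(
    text: str, sample_order: Optional[Sequence[str]] = None
) -> Node:
    """Parse a genotype-filter expression into an AST.

    When ``sample_order`` is given, sample names are validated eagerly.
    """
    if not text or not text.strip():
        raise GtFilterSyntaxError("empty genotype filter")
    return _Parser(_tokenize(text), sample_order).parse()


# ---------------------------------------------------------------------------
# evaluation

_UNCALLED_GTS = {".", "./.", ".|."}


def _compare(op: str, left, right) -> bool:
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    return left >= right


def _eval_cmp(cmp: Comparison, arrays: dict, index: int, strict: bool) -> bool:
    value = arrays[cmp.column][index]
    if cmp.column == "gts":
        missing = value in _UNCALLED_GTS
        literal_called = cmp.literal not in _UNCALLED_GTS
    elif cmp.column == "gt_types":
        missing = value == UNKNOWN
        literal_called = cmp.literal != UNKNOWN
    elif cmp.column == "gt_depths":
        missing = value == -1
        literal_called = True
        if not strict:
            return _compare(cmp.op, value, cmp.literal)  # numeric semantics
    else:  # gt_phases: no missing state
        return _compare(cmp.op, bool(value), cmp.literal)
    if missing and literal_called:
        if strict:
            return False
        return cmp.op == "!="
    if missing and strict:
        return False
    return _compare(cmp.op, value, cmp.literal)


def evaluate_filter(
    node: Node,
    arrays: dict,
    sample_index: dict[str, int],
    strict_missing: bool = False,
) -> bool:
    """Evaluate an AST against one variant's unpacked genotype arrays.

    ``arrays`` maps each of the four column names to its per-sample list;
    ``sample_index`` maps sample ids to positions.
    """
    if isinstance(node, Comparison):
        try:
            idx = sample_index[node.sample]
        except KeyError:
            raise UnknownSampleError(f"unknown sample {node.sample!r}") from None
        return _eval_cmp(node, arrays, idx, strict_missing)
    if isinstance(node, Not):
        return not evaluate_filter(node.child, arrays, sample_index, strict_missing)
    if isinstance(node, And):
        return all(
            evaluate_filter(c, arrays, sample_index, strict_missing)
            for c in node.children
        )
    if isinstance(node, Or):
        return any(
            evaluate_filter(c, arrays, sample_index, strict_missing)
            for c in node.children
        )
    raise TypeError(f"not an AST node: {node!r}")


def same_genotype_for_all(
    column: str, op: str, literal, samples: Sequence[str], combine: str = "and"
) -> Node:
    """Convenience builder: the same condition over several samples.

    ``combine='and'`` requires it of every sample ("all affected are HET"),
    ``'or'`` of at least one. This is a library helper, not DSL syntax.
    """
    if column not in GT_COLUMNS:
        raise ValueError(f"unknown column {column!r}")
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}")
    parts = tuple(Comparison(column, s, op, literal) for s in samples)
    if len(parts) == 1:
        return parts[0]
    return And(parts) if combine == "and" else Or(parts)


# ---------------------------------------------------------------------------
# execution

_PSEUDO_RE = re.compile(r"^(gts|gt_types|gt_phases|gt_depths)\.([\w.\-]+)$")
_SELECT_RE = re.compile(r"^\s*select\s+(.*?)\s+from\s+", re.IGNORECASE | re.DOTALL)


def _split_select_list(text: str) -> list[str]:
    items, depth, current = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            items.append("".join(current).strip())
            current = []
        else:
            current.append(ch)
    if current:
        items.append("".join(current).strip())
    return [i for i in items if i]


def expand_sample_columns(
    select_items: Sequence[str],
    row: dict,
    arrays: dict,
    sample_index: dict[str, int],
) -> list:
    """Materialize one output row: COLUMN.SAMPLE items become per-sample
    values from the unpacked arrays; other items pass through from ``row``."""
    out = []
    for item in select_items:
        m = _PSEUDO_RE.match(item)
        if m:
            column, sample = m.groups()
            try:
                idx = sample_index[sample]
            except KeyError:
                raise UnknownSampleError(f"unknown sample {sample!r}") from None
            out.append(arrays[column][idx])
        else:
            out.append(row[item])
    return out


def execute_query(handle: DatabaseHandle, request: QueryRequest) -> Iterator[tuple]:
    """Run SQL, then apply the genotype filter row by row.

    Yields result tuples (a header tuple first when requested). Raw blob
    columns never appear in the output: ``select *`` expands to all
    non-blob columns, and genotype material is reached through
    COLUMN.SAMPLE pseudo-columns.
    """
    sample_index = {s: i for i, s in enumerate(handle.sample_order)}
    ast = (
        parse_gt_filter(request.gt_filter, handle.sample_order)
        if request.gt_filter
        else None
    )

    m = _SELECT_RE.match(request.sql)
    if not m:
        raise ValueError("only SELECT statements are supported")
    select_items = _split_select_list(m.group(1))
    tail = request.sql[m.end(1):]

    inner_items, output_plan = [], []  # plan: ("pseudo", col, sample) | ("alias", name) | ("star",)
    for n, item in enumerate(select_items):
        pm = _PSEUDO_RE.match(item)
        if pm:
            column, sample = pm.groups()
            if sample not in sample_index:
                raise UnknownSampleError(f"unknown sample {sample!r}")
            inner_items.append(f'"{column}" AS __vh_c{n}')
            output_plan.append(("pseudo", column, sample, item))
        elif item == "*":
            inner_items.append("*")
            output_plan.append(("star",))
        else:
            alias = f"__vh_c{n}"
            inner_items.append(f"{item} AS {alias}")
            output_plan.append(("alias", alias, item))
    need_arrays = ast is not None or any(p[0] == "pseudo" for p in output_plan)
    has_star = any(p[0] == "star" for p in output_plan)
    if need_arrays and not has_star:
        inner_items += [f'"{c}" AS __vh_f_{c}' for c in GT_COLUMNS]

    sql = "SELECT " + ", ".join(inner_items) + tail
    conn = handle.connect()
    try:
        try:
            cursor = conn.execute(sql)
        except sqlite3.Error as exc:
            raise RuntimeError(f"SQL error: {exc}\nstatement: {request.sql}") from exc
        columns = [d[0] for d in cursor.description]
        star_columns = [
            c for c in columns if c not in GT_COLUMNS and not c.startswith("__vh_")
        ]
        if request.show_header:
            header: list[str] = []
            for plan in output_plan:
                if plan[0] == "star":
                    header.extend(star_columns)
                elif plan[0] == "pseudo":
                    header.append(plan[3])
                else:
                    header.append(plan[2])
            yield tuple(header)
        for raw in cursor:
            row = dict(zip(columns, raw))
            arrays = None
            if need_arrays:
                arrays = {
                    c: unpack(row[c] if has_star else row[f"__vh_f_{c}"])
                    for c in GT_COLUMNS
                }
            if ast is not None and not evaluate_filter(
                ast, arrays, sample_index, request.strict_missing
            ):
                continue
            out = []
            for plan in output_plan:
                if plan[0] == "star":
                    out.extend(row[c] for c in star_columns)
                elif plan[0] == "pseudo":
                    out.append(arrays[plan[1]][sample_index[plan[2]]])
                else:
                    out.append(row[plan[1]])
            yield tuple(out)
    finally:
        conn.close()
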