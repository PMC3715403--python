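"""Genotype-filter DSL parsing/evaluation and query execution vs brute force."""

import random
import sqlite3

import pytest

from varhive import load, open_handle, simulate
from varhive.gtstore import GenotypeRow, unpack
from varhive.query import (
    And,
    Comparison,
    GtFilterSyntaxError,
    Not,
    Or,
    QueryRequest,
    UnknownSampleError,
    evaluate_filter,
    execute_query,
    expand_sample_columns,
    parse_gt_filter,
    same_genotype_for_all,
)

# ---------------------------------------------------------------------------
# an independent, deliberately naive interpreter used as the oracle

UNCALLED = {".", "./.", ".|."}


def naive_eval(node, arrays, index, strict=False):
    if isinstance(node, Not):
        return not naive_eval(node.child, arrays, index, strict)
    if isinstance(node, And):
        result = True
        for c in node.children:
            result = result and naive_eval(c, arrays, index, strict)
        return result
    if isinstance(node, Or):
        result = False
        for c in node.children:
            result = result or naive_eval(c, arrays, index, strict)
        return result
    value = arrays[node.column][index[node.sample]]
    if node.column == "gts":
        missing, lit_called = value in UNCALLED, node.literal not in UNCALLED
    elif node.column == "gt_types":
        missing, lit_called = value == 2, node.literal != 2
    elif node.column == "gt_depths":
        if strict and value == -1:
            return False
        missing, lit_called = False, True
    else:
        missing, lit_called = False, True
        value = bool(value)
    if missing and strict:
        return False
    if missing and lit_called:
        return node.op == "!="
    table = {
        "==": value == node.literal,
        "!=": value != node.literal,
        "<": value < node.literal,
        "<=": value <= node.literal,
        ">": value > node.literal,
        ">=": value >= node.literal,
    }
    return table[node.op]


class TestParser:
    def test_single_comparison_with_keyword_literal(self):
        ast = parse_gt_filter("gt_types.NA12878 == HET")
        assert ast == Comparison("gt_types", "NA12878", "==", 1)

    def test_spaced_equality_spelling_accepted(self):
        assert parse_gt_filter("gt_types.NA12878 =  = HET") == parse_gt_filter(
            "gt_types.NA12878 == HET"
        )

    def test_trio_conjunction(self):
        ast = parse_gt_filter(
            "gt_types.mom == HET and gt_types.dad == HET "
            "and gt_types.proband == HOM_ALT"
        )
        assert isinstance(ast, And) and len(ast.children) == 3
        assert ast.children[2] == Comparison("gt_types", "proband", "==", 3)

    def test_not_and_parentheses(self):
        ast = parse_gt_filter("not (gt_depths.kid >= 10)")
        assert ast == Not(Comparison("gt_depths", "kid", ">=", 10))

    def test_precedence_and_binds_tighter_than_or(self):
        ast = parse_gt_filter(
            "gt_types.a == HET or gt_types.b == HET and gt_types.c == HET"
        )
        assert isinstance(ast, Or)
        assert isinstance(ast.children[1], And)

    def test_keywords_are_case_insensitive(self):
        assert parse_gt_filter("gt_types.s == het") == Comparison(
            "gt_types", "s", "==", 1
        )

    def test_gts_string_literal(self):
        assert parse_gt_filter("gts.kid == 'A/G'") == Comparison(
            "gts", "kid", "==", "A/G"
        )
        assert parse_gt_filter("gts.kid != ./.") == Comparison(
            "gts", "kid", "!=", "./."
        )

    def test_unknown_column_names_valid_ones(self):
        with pytest.raises(GtFilterSyntaxError, match="gt_depths"):
            parse_gt_filter("gt_quality.kid == 3")

    def test_unknown_sample_named_when_order_given(self):
        with pytest.raises(UnknownSampleError, match="ghost"):
            parse_gt_filter("gt_types.ghost == HET", sample_order=["kid"])

    def test_syntax_error_carries_position(self):
        with pytest.raises(GtFilterSyntaxError, match="position"):
            parse_gt_filter("gt_types.kid == HET and")

    def test_empty_filter_rejected(self):
        with pytest.raises(GtFilterSyntaxError):
            parse_gt_filter("   ")


def make_arrays(gts, types, phases, depths):
    return {"gts": gts, "gt_types": types, "gt_phases": phases, "gt_depths": depths}


class TestEvaluation:
    INDEX = {"kid": 0, "mom": 1, "dad": 2}

    def test_het_match(self):
        arrays = make_arrays(
            ["A/G", "A/A", "A/A"], [1, 0, 0], [False] * 3, [20, 30, 40]
        )
        ast = parse_gt_filter("gt_types.kid == HET")
        assert evaluate_filter(ast, arrays, self.INDEX)

    def test_unknown_genotype_fails_equality_but_passes_inequality(self):
        arrays = make_arrays(["./.", "A/A", "A/A"], [2, 0, 0], [False] * 3, [-1, 9, 9])
        assert not evaluate_filter(
            parse_gt_filter("gt_types.kid == HET"), arrays, self.INDEX
        )
        assert evaluate_filter(
            parse_gt_filter("gt_types.kid != HET"), arrays, self.INDEX
        )
        assert evaluate_filter(
            parse_gt_filter("gt_types.kid == UNKNOWN"), arrays, self.INDEX
        )

    def test_missing_depth_numeric_vs_strict(self):
        arrays = make_arrays(["A/G"], [1], [False], [-1])
        ast = parse_gt_filter("gt_depths.kid < 10")
        assert evaluate_filter(ast, arrays, {"kid": 0})
        assert not evaluate_filter(ast, arrays, {"kid": 0}, strict_missing=True)

    def test_random_asts_agree_with_naive_interpreter(self):
        rng = random.Random(2024)
        samples = ["kid", "mom", "dad", "sib"]
        index = {s: i for i, s in enumerate(samples)}

        def rand_cmp():
            col = rng.choice(["gts", "gt_types", "gt_phases", "gt_depths"])
            sample = rng.choice(samples)
            op = rng.choice(["==", "!=", "<", "<=", ">", ">="])
            if col == "gts":
                lit = rng.choice(["A/G", "A/A", "./.", "G|G"])
                op = rng.choice(["==", "!="])
            elif col == "gt_types":
                lit = rng.choice([0, 1, 2, 3])
            elif col == "gt_phases":
                lit = rng.choice([True, False])
                op = rng.choice(["==", "!="])
            else:
                lit = rng.randrange(-1, 60)
            return Comparison(col, sample, op, lit)

        def rand_ast(depth):
            if depth == 0 or rng.random() < 0.4:
                return rand_cmp()
            kind = rng.choice(["and", "or", "not"])
            if kind == "not":
                return Not(rand_ast(depth - 1))
            children = tuple(rand_ast(depth - 1) for _ in range(rng.randrange(2, 4)))
            return And(children) if kind == "and" else Or(children)

        for _ in range(1000):
            ast = rand_ast(3)
            arrays = make_arrays(
                [rng.choice(["A/G", "A/A", "G/G", "./.", "G|G"]) for _ in samples],
                [rng.choice([0, 1, 2, 3]) for _ in samples],
                [rng.random() < 0.5 for _ in samples],
                [rng.randrange(-1, 60) for _ in samples],
            )
            strict = rng.random() < 0.3
            assert evaluate_filter(ast, arrays, index, strict) == naive_eval(
                ast, arrays, index, strict
            )

    def test_convenience_builder_all_samples(self):
        ast = same_genotype_for_all("gt_types", "==", 1, ["a", "b"])
        assert ast == And(
            (Comparison("gt_types", "a", "==", 1), Comparison("gt_types", "b", "==", 1))
        )


class TestExpandSampleColumns:
    def test_pseudo_columns_replaced(self):
        arrays = make_arrays(["A/G", "A/A"], [1, 0], [False, False], [9, 9])
        out = expand_sample_columns(
            ["chrom", "gts.kid"], {"chrom": "chr1"}, arrays, {"kid": 0, "mom": 1}
        )
        assert out == ["chr1", "A/G"]

    def test_no_pseudo_columns_pass_through(self):
        out = expand_sample_columns(
            ["chrom", "start"], {"chrom": "chr1", "start": 5}, {}, {}
        )
        assert out == ["chr1", 5]

    def test_all_samples_equals_full_unpack(self):
        arrays = make_arrays(["A/G", "A/A", "G/G"], [1, 0, 3], [False] * 3, [1, 2, 3])
        index = {"a": 0, "b": 1, "c": 2}
        out = expand_sample_columns(
            [f"gt_types.{s}" for s in ("a", "b", "c")], {}, arrays, index
        )
        assert out == arrays["gt_types"]


@pytest.fixture(scope="module")
def query_db(tmp_path_factory):
    out = tmp_path_factory.mktemp("querydb")
    fx = simulate.simulate_cohort(
        simulate.CohortSpec(n_samples=8, n_variants=400, missingness=0.08, seed=13),
        str(out),
    )
    db = str(out / "q.db")
    load(db, fx["vcf"])
    return db, fx


def full_scan(db):
    """Raw table contents with genotype arrays unpacked, for the oracle."""
    conn = sqlite3.connect(db)
    conn.row_factory = sqlite3.Row
    rows = []
    for r in conn.execute("SELECT * FROM variants ORDER BY variant_id"):
        d = dict(r)
        for c in ("gts", "gt_types", "gt_phases", "gt_depths"):
            d[c] = unpack(d[c])
        rows.append(d)
    conn.close()
    return rows


class TestExecuteQuery:
    def test_sql_only_rare_lof_pattern(self, family_fixture):
        rows = list(
            execute_query(
                open_handle(family_fixture["db"]),
                QueryRequest(
                    sql="select variant_id from variants "
                    "where impact_severity = 'MED' and aaf < 0.2"
                ),
            )
        )
        scan = full_scan(family_fixture["db"])
        expected = {
            r["variant_id"]
            for r in scan
            if r["impact_severity"] == "MED" and (r["aaf"] or 0) < 0.2
        }
        assert {r[0] for r in rows} == expected and expected

    def test_gt_filter_prunes_not_widens(self, query_db):
        db, _ = query_db
        handle = open_handle(db)
        base = {
            r[0]
            for r in execute_query(
                handle, QueryRequest(sql="select variant_id from variants where aaf > 0.1")
            )
        }
        filtered = {
            r[0]
            for r in execute_query(
                handle,
                QueryRequest(
                    sql="select variant_id from variants where aaf > 0.1",
                    gt_filter="gt_types.S000 == HET",
                ),
            )
        }
        assert filtered <= base

    def test_unsatisfiable_filter_returns_nothing(self, query_db):
        db, _ = query_db
        rows = list(
            execute_query(
                open_handle(db),
                QueryRequest(
                    sql="select variant_id from variants",
                    gt_filter="gt_types.S000 == HET and gt_types.S000 == HOM_ALT",
                ),
            )
        )
        assert rows == []

    def test_header_row_matches_select_list(self, query_db):
        db, _ = query_db
        rows = list(
            execute_query(
                open_handle(db),
                QueryRequest(
                    sql="select chrom, start, gts.S001 from variants limit 1",
                    show_header=True,
                ),
            )
        )
        assert rows[0] == ("chrom", "start", "gts.S001")

    def test_select_star_excludes_raw_blob_columns(self, query_db):
        db, _ = query_db
        header, first = list(
            execute_query(
                open_handle(db),
                QueryRequest(sql="select * from variants limit 1", show_header=True),
            )
        )
        assert "gts" not in header and "gt_types" not in header
        assert len(header) == len(first)

    def test_sql_error_surfaces_statement(self, query_db):
        db, _ = query_db
        with pytest.raises(RuntimeError, match="no_such_column"):
            list(
                execute_query(
                    open_handle(db),
                    QueryRequest(sql="select no_such_column from variants"),
                )
            )

    def test_randomized_queries_match_brute_force(self, query_db):
        """Random WHERE clauses + genotype filters against an in-memory
        full-table scan with an independent filter interpreter."""
        db, fx = query_db
        handle = open_handle(db)
        scan = full_scan(db)
        samples = fx["samples"]
        index = {s: i for i, s in enumerate(samples)}
        rng = random.Random(31)

        numeric_cols = ["aaf", "call_rate", "num_het", "num_hom_alt", "start"]
        for _ in range(50):
            col = rng.choice(numeric_cols)
            op = rng.choice(["<", "<=", ">", ">=", "="])
            thr = {
                "aaf": round(rng.uniform(0, 1), 3),
                "call_rate": round(rng.uniform(0.7, 1), 3),
                "num_het": rng.randrange(0, 8),
                "num_hom_alt": rng.randrange(0, 8),
                "start": rng.randrange(0, 400_000),
            }[col]
            where = f"{col} {op} {thr}"
            sample = rng.choice(samples)
            gt_choice = rng.choice(
                [
                    f"gt_types.{sample} == HET",
                    f"gt_types.{sample} == HOM_ALT",
                    f"gt_types.{sample} != HOM_REF",
                    f"gt_depths.{sample} >= {rng.randrange(5, 40)}",
                    f"gt_types.{sample} == HET or gt_types.{rng.choice(samples)} == HOM_ALT",
                ]
            )
            got = {
                r[0]
                for r in execute_query(
                    handle,
                    QueryRequest(
                        sql=f"select variant_id from variants where {where}",
                        gt_filter=gt_choice,
                    ),
                )
            }
            ast = parse_gt_filter(gt_choice)
            py_op = {"<": "__lt__", "<=": "__le__", ">": "__gt__", ">=": "__ge__", "=": "__eq__"}[op]
            expected = set()
            for r in scan:
                v = r[col]
                if v is None or not getattr(v, py_op)(thr):
                    continue
                if naive_eval(ast, r, index):
                    expected.add(r["variant_id"])
            assert got == expected
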