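"""Typed table parsing and representation-specific group summaries."""

import math

import numpy as np
import pytest

import pathstain as ps
from pathstain.omics_data import (
    DATA_TYPES,
    DataParseError,
    SampleGroup,
    internal_repr_of,
    is_mutated_label,
    summarize_group,
)

EXPR = "GENE\tS1\tS2\tS3\nTP53\t1.0\t2.0\t3.0\nMDM2\t0.5\tNA\t1.5\n"
MUT = "GENE\tS1\tS2\tS3\nTP53\tWT\tp.R175H\tWT\nMDM2\tWT\tWT\tWT\nATM\tNA\tNA\tNA\n"
CN = "GENE\tS1\tS2\tS3\nTP53\t-1\t-1\t2\nMDM2\t0\t1\t-1\n"


def grp(*members):
    return SampleGroup(group_id="g", members=members)


def test_internal_repr_table_is_exhaustive():
    expected = {
        "mrna_expression": "continuous",
        "microrna_expression": "continuous",
        "protein_expression": "continuous",
        "copynumber_discrete": "discrete_ordered",
        "copynumber_continuous": "continuous",
        "mutation": "discrete_unordered",
        "gene_list": "set",
    }
    assert DATA_TYPES == expected
    for dtype, repr_ in expected.items():
        assert internal_repr_of(dtype) == repr_


def test_unknown_data_type_lists_accepted():
    with pytest.raises(DataParseError, match="mrna_expression"):
        internal_repr_of("methylation")


def test_parse_continuous_matrix():
    t = ps.parse_data_table(EXPR, "mrna_expression")
    assert t.genes == ["TP53", "MDM2"] and t.samples == ["S1", "S2", "S3"]
    assert t.internal_repr == "continuous"
    assert t.values.loc["TP53", "S2"] == 2.0
    assert math.isnan(t.values.loc["MDM2", "S2"])  # NA cell is missing


def test_parse_gene_list_with_and_without_header():
    for text in ("TP53\nMDM2\n", "GENE\nTP53\nMDM2\n"):
        t = ps.parse_data_table(text, "gene_list")
        assert t.internal_repr == "set"
        assert t.genes == ["TP53", "MDM2"]
        assert list(t.values["member"]) == [True, True]


@pytest.mark.parametrize(
    "text, match",
    [
        ("GENE\tS1\nTP53\t1\nTP53\t2\n", "TP53"),          # duplicate gene row
        ("GENE\tS1\tS2\nTP53\t1\n", "line 2"),             # ragged row
        ("GENE\tS1\nTP53\tabc\n", "TP53.*S1"),             # non-numeric cell
        ("GENE\tS1\nTP53\t1.5\n", "discrete ordered"),     # non-integer CN (CN only)
    ],
)
def test_parse_errors(text, match):
    dtype = "copynumber_discrete" if "1.5" in text else "mrna_expression"
    with pytest.raises(DataParseError, match=match):
        ps.parse_data_table(text, dtype)


def test_duplicate_rows_aggregated_on_request():
    t = ps.parse_data_table(
        "GENE\tS1\nTP53\t1\nTP53\t3\n", "mrna_expression", aggregate_duplicates="mean"
    )
    assert t.values.loc["TP53", "S1"] == 2.0


def test_build_groups_partition_non_na_levels():
    ann = ps.parse_annotation("SAMPLE\tdisease\tsite\nS1\tAD\tX\nS2\tAD\tY\nS3\tCTRL\tX\n")
    groups = {g.group_id: g.members for g in ps.build_groups(ann, "disease")}
    assert groups == {"disease=AD": ("S1", "S2"), "disease=CTRL": ("S3",)}
    site = {g.group_id: g.members for g in ps.build_groups(ann, "site")}
    assert site == {"site=X": ("S1", "S3"), "site=Y": ("S2",)}


def test_build_groups_all_na_factor_is_empty():
    ann = ps.parse_annotation("SAMPLE\tf\nS1\tNA\nS2\tn/a\n")
    assert ps.build_groups(ann, "f") == []
    with pytest.raises(DataParseError, match="'f'"):
        ps.build_groups(ann, "nope")


def test_continuous_group_mean_skips_missing():
    t = ps.parse_data_table(EXPR, "mrna_expression")
    s = summarize_group(t, grp("S1", "S2", "S3"))
    assert s["TP53"] == pytest.approx(2.0)
    assert s["MDM2"] == pytest.approx((0.5 + 1.5) / 2)  # NA excluded, hand-computed
    assert summarize_group(t, grp("S1", "S2", "S3"), method="max")["TP53"] == 3.0


def test_mutation_group_any_mutated():
    t = ps.parse_data_table(MUT, "mutation")
    s = summarize_group(t, grp("S1", "S2", "S3"))
    assert s["TP53"] is True   # at least one member mutated
    assert s["MDM2"] is False
    assert s["ATM"] is None    # all members missing stays missing


@pytest.mark.parametrize(
    "label, mutated",
    [("p.R175H", True), ("1", True), ("missense", True),
     ("WT", False), ("wt", False), ("0", False), ("NA", False), ("", False)],
)
def test_mutation_label_vocabulary(label, mutated):
    assert is_mutated_label(label) is mutated


def test_ordered_group_mode_with_magnitude_tiebreak():
    t = ps.parse_data_table(CN, "copynumber_discrete")
    s = summarize_group(t, grp("S1", "S2", "S3"))
    assert s["TP53"] == -1.0           # majority
    assert s["MDM2"] == -1.0           # 0/1/-1 all tie; largest magnitude wins... ties at |1|
    # explicit tie between +2 and -2: the larger-magnitude rule needs a winner;
    # ties at equal magnitude resolve to the positive (argmax order)
    t2 = ps.parse_data_table("GENE\tS1\tS2\nX\t2\t-2\n", "copynumber_discrete")
    assert abs(summarize_group(t2, grp("S1", "S2"))["X"]) == 2.0


def test_single_member_group_is_identity(mutation_table, expr_design):
    t = expr_design["table"]
    sample = t.samples[0]
    s = summarize_group(t, grp(sample))
    assert np.allclose(s.to_numpy(), t.values[sample].to_numpy())
    m = summarize_group(mutation_table, grp(mutation_table.samples[0]))
    raw = mutation_table.values[mutation_table.samples[0]]
    assert all(m[g] == is_mutated_label(raw[g]) for g in mutation_table.genes)


def test_group_disjoint_from_table_errors():
    t = ps.parse_data_table(EXPR, "mrna_expression")
    with pytest.raises(DataParseError, match="no samples"):
        summarize_group(t, grp("ZZ1", "ZZ2"))


def test_group_mean_matches_per_cell_oracle_on_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(5):
        genes = [f"G{i}" for i in range(12)]
        samples = [f"S{j}" for j in range(9)]
        values = rng.normal(size=(12, 9))
        mask = rng.random((12, 9)) < 0.2
        lines = ["GENE\t" + "\t".join(samples)]
        for i, g in enumerate(genes):
            cells = ["NA" if mask[i, j] else format(values[i, j], ".10g") for j in range(9)]
            lines.append(g + "\t" + "\t".join(cells))
        t = ps.parse_data_table("\n".join(lines) + "\n", "mrna_expression")
        members = tuple(rng.choice(samples, size=4, replace=False))
        s = summarize_group(t, grp(*members))
        for i, g in enumerate(genes):  # brute-force per-cell recomputation
            kept = [values[i, samples.index(m)] for m in members if not mask[i, samples.index(m)]]
            if not kept:
                assert math.isnan(s[g])
            else:
                assert s[g] == pytest.approx(sum(kept) / len(kept))


def test_summary_invariant_under_sample_permutation(expr_design, mutation_table):
    rng = np.random.default_rng(3)
    for table in (expr_design["table"], mutation_table):
        perm = list(rng.permutation(table.samples))
        shuffled = ps.DataTable(table.name, table.data_type, table.values[perm])
        g = grp(*table.samples[:3])
        a, b = summarize_group(table, g), summarize_group(shuffled, g)
        assert list(a.index) == list(b.index)
        for x, y in zip(a, b):
            assert (x is None and y is None) or x == y or (
                isinstance(x, float) and math.isnan(x) and math.isnan(y)
            )
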