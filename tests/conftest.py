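import pytest

import pathstain as ps
from pathstain.fixtures import (
    FixtureSpec,
    make_expression_table,
    make_grid_map,
    make_mutation_table,
)


@pytest.fixture(scope="session")
def grid_map():
    return make_grid_map(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def expr_design(grid_map):
    """Expression matrix with module mod1 up-shifted by 2.0 in the disease
    group (sd 0.5), plus the matching annotation; parsed forms included."""
    matrix_text, annotation_text = make_expression_table(
        grid_map,
        group_sizes={"disease": 4, "control": 4},
        module_effects={"disease": {"mod1": 2.0}},
        noise_sd=0.5,
        seed=21,
    )
    table = ps.parse_data_table(matrix_text, "mrna_expression", name="EXPR")
    annotation = ps.parse_annotation(annotation_text)
    groups = ps.build_groups(annotation, "group")
    return {
        "matrix_text": matrix_text,
        "annotation_text": annotation_text,
        "table": table,
        "annotation": annotation,
        "groups": {g.group_id: g for g in groups},
    }


@pytest.fixture(scope="session")
def mutation_table(grid_map, expr_design):
    text = make_mutation_table(grid_map, 0.3, expr_design["table"].samples, seed=31)
    return ps.parse_data_table(text, "mutation", name="MUT")


@pytest.fixture()
def tiny_map():
    return ps.loads_map(
        """
        {"name": "tiny", "canvas": {"width": 400, "height": 300, "max_zoom": 2},
         "entities": [
           {"id": "p53", "label": "TP53", "class": "protein", "hugo": ["TP53"],
            "x": 100, "y": 80, "w": 30, "h": 14, "modules": ["apoptosis"], "min_zoom": 0},
           {"id": "mdm2", "label": "MDM2", "class": "protein", "hugo": ["MDM2"],
            "x": 220, "y": 90, "w": 30, "h": 14, "modules": ["apoptosis"], "min_zoom": 0},
           {"id": "cplx", "label": "TP53:MDM2", "class": "complex",
            "hugo": ["TP53", "MDM2"], "x": 160, "y": 200, "w": 44, "h": 18,
            "modules": ["apoptosis"], "min_zoom": 1},
           {"id": "growth", "label": "growth", "class": "phenotype", "hugo": [],
            "x": 320, "y": 220, "w": 40, "h": 16, "modules": ["fate"], "min_zoom": 2}
         ],
         "modules": [
           {"id": "apoptosis", "name": "Apoptosis", "members": ["p53", "mdm2", "cplx"]},
           {"id": "fate", "name": "Cell fate", "members": ["growth"]}
         ]}
        """
    )
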