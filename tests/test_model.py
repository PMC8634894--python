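import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actnet import fixtures
from actnet.model import (
    EdgeSpec,
    FateClassifier,
    ModelParseError,
    ModelValidationError,
    NetworkModel,
    NodeSpec,
    apply_clamps,
    contract_nodes,
    dumps_model,
    export_graphml,
    export_sif,
    load_model,
    loads_model,
    save_model,
    scale_downstream,
)


class TestLoadModel:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({"nodes": [{"name": "A"}], "edges": []}))
        m = load_model(path)
        assert len(m.nodes) == 1 and len(m.edges) == 0
        assert m.nodes[0].levels == 100 and m.nodes[0].initial == 0

    def test_unknown_node_in_edge_names_it(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(
            json.dumps(
                {
                    "nodes": [{"name": "A"}],
                    "edges": [{"regulators": ["X"], "target": "A", "k": 1.0}],
                }
            )
        )
        with pytest.raises(ModelValidationError, match="'X'"):
            load_model(path)

    def test_bundled_ras_fixture_file(self):
        m = load_model(fixtures.fixture_path("ras_motif"))
        assert len(m.nodes) == 5 and len(m.edges) == 5
        activations = [e for e in m.edges if e.sign == "activation"]
        loops = [e for e in m.edges if e.is_self_inhibition]
        assert len(activations) == 4
        assert all(e.k == 0.444 for e in activations)
        assert len(loops) == 1 and loops[0].k == 1.0

    def test_parse_error_carries_context(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelParseError, match="line"):
            load_model(path)

    def test_missing_k_is_parse_error(self):
        doc = {
            "nodes": [{"name": "A"}],
            "edges": [{"regulators": ["A"], "target": "A"}],
        }
        with pytest.raises(ModelParseError, match="'k'"):
            loads_model(json.dumps(doc))

    def test_validation_lists_every_violation(self):
        m = NetworkModel(
            nodes=[NodeSpec("A", initial=150), NodeSpec("A")],
            edges=[EdgeSpec(("Z",), "A", k=-1.0)],
        )
        with pytest.raises(ModelValidationError) as err:
            m.validate()
        text = str(err.value)
        assert "duplicate" in text and "initial" in text
        assert "'Z'" in text and "k must be" in text


class TestSaveAndExport:
    def test_round_trip_ras(self, ras_motif, tmp_path):
        path = tmp_path / "ras.json"
        save_model(ras_motif, path)
        again = load_model(path)
        assert again.structurally_equal(ras_motif)

    def test_sif_distinct_relation_tokens(self, abc_example):
        rows = export_sif(abc_example).strip().splitlines()
        assert "A\tactivates\tB" in rows
        assert "C\tinhibits\tB" in rows

    def test_sif_scenario3_single_record(self):
        m = fixtures.motif("and_gate")
        rows = export_sif(m).strip().splitlines()
        (and_row,) = [r for r in rows if "&" in r]
        src, rel, tgt = and_row.split("\t")
        assert set(src.split("&")) == {"A", "B"}
        assert rel == "activates" and tgt == "C"

    def test_graphml_carries_scenario_and_k(self, ras_motif):
        text = export_graphml(ras_motif)
        assert "scenario" in text and '"k"' in text.replace("'", '"')
        assert "interaction" in text

    def test_graphml_writes_file(self, ras_motif, tmp_path):
        out = tmp_path / "m.graphml"
        export_graphml(ras_motif, out)
        assert out.read_text().startswith("<graphml")


class TestApplyClamps:
    def test_clamp_is_constant_in_simulation(self, ras_motif):
        from actnet.simulate import simulate

        m = apply_clamps(ras_motif, {"Wnt": 100})
        tr = simulate(m)
        assert all(node != "Wnt" for _, node, _ in tr.events)
        assert tr.final["Wnt"] == 100

    def test_clamp_zero_still_drives_downstream(self, abc_example):
        from actnet.simulate import SimState, net_rate

        m = apply_clamps(abc_example, {"C": 0})
        state = SimState.from_model(m)
        # C inhibition contributes 0, A at 100 contributes +0.5
        assert net_rate(m, "B", state) == pytest.approx(0.5)

    def test_empty_clamp_is_identity(self, ras_motif):
        assert apply_clamps(ras_motif, {}).structurally_equal(ras_motif)

    def test_unknown_node_rejected(self, ras_motif):
        with pytest.raises(KeyError):
            apply_clamps(ras_motif, {"nope": 0})

    def test_out_of_range_clamp_rejected(self, ras_motif):
        with pytest.raises(ModelValidationError):
            apply_clamps(ras_motif, {"Wnt": 101})


class TestScaleDownstream:
    def test_scaling_factor_applied_to_outgoing(self, mini_chondro):
        scaled = scale_downstream(mini_chondro, "X", 0.64)
        for before, after in zip(mini_chondro.edges, scaled.edges):
            if "X" in before.regulators and not before.is_self_inhibition:
                assert after.k == pytest.approx(0.64 * before.k)
            else:
                assert after.k == before.k

    def test_self_inhibition_untouched(self, ras_motif):
        scaled = scale_downstream(ras_motif, "Ras", 0.64)
        (loop,) = [e for e in scaled.edges if e.is_self_inhibition]
        assert loop.k == 1.0

    def test_factor_one_is_identity(self, ras_motif):
        assert scale_downstream(ras_motif, "Wnt", 1.0).structurally_equal(
            ras_motif
        )

    def test_inverse_restores_k(self, mini_chondro):
        f = 0.64
        back = scale_downstream(
            scale_downstream(mini_chondro, "X", f), "X", 1.0 / f
        )
        for a, b in zip(mini_chondro.edges, back.edges):
            assert b.k == pytest.approx(a.k)

    def test_unknown_node(self, ras_motif):
        with pytest.raises(KeyError):
            scale_downstream(ras_motif, "nope", 0.5)

    def test_counts_unchanged(self, mini_chondro):
        scaled = scale_downstream(mini_chondro, "X", 0.5)
        assert len(scaled.nodes) == len(mini_chondro.nodes)
        assert len(scaled.edges) == len(mini_chondro.edges)


class TestContractNodes:
    @staticmethod
    def _chain():
        return NetworkModel(
            nodes=[NodeSpec("X"), NodeSpec("prom"), NodeSpec("prot")],
            edges=[
                EdgeSpec(("X",), "prom", "activation", 1, 0.1),
                EdgeSpec(("prom",), "prom", "inhibition", 1, 0.1),
                EdgeSpec(("prom",), "prot", "activation", 1, 0.1),
            ],
        )

    def test_chain_contraction(self):
        out = contract_nodes(self._chain(), {"prom"})
        assert out.node_names() == ["X", "prot"]
        (edge,) = out.edges
        assert edge.regulators == ("X",) and edge.target == "prot"
        assert edge.k == 0.1 and edge.sign == "activation"

    def test_empty_contraction_is_identity(self, ras_motif):
        assert contract_nodes(ras_motif, set()).structurally_equal(ras_motif)

    def test_two_successors_rejected(self):
        m = self._chain()
        m.edges.append(EdgeSpec(("prom",), "X", "activation", 1, 0.1))
        with pytest.raises(ModelValidationError, match="exactly one"):
            contract_nodes(m, {"prom"})


class TestFateClassifier:
    def test_two_fate_rules(self):
        cls = FateClassifier.two_fate()
        assert cls.classify({"SOX9": 88, "RUNX2": 0}) == "SOX9+"
        assert cls.classify({"SOX9": 0, "RUNX2": 100}) == "RUNX2+"
        assert cls.classify({"SOX9": 0, "RUNX2": 0}) == "Null"
        assert cls.classify({"SOX9": 50, "RUNX2": 50}) == "other"

    def test_duplicate_labels_rejected(self):
        from actnet.predicates import AllZeroPredicate

        with pytest.raises(ValueError):
            FateClassifier(
                rules=[("a", AllZeroPredicate()), ("a", AllZeroPredicate())]
            )


# --- property tests -------------------------------------------------------

_names = st.lists(
    st.text(alphabet="ABCDEFGH", min_size=1, max_size=3),
    min_size=1,
    max_size=6,
    unique=True,
)


@st.composite
def models(draw):
    names = draw(_names)
    nodes = []
    for name in names:
        levels = draw(st.integers(min_value=1, max_value=200))
        nodes.append(
            NodeSpec(
                name,
                levels=levels,
                initial=draw(st.integers(0, levels)),
                clamp=draw(st.one_of(st.none(), st.integers(0, levels))),
                reaction_class=draw(st.sampled_from(["slow", "fast"])),
            )
        )
    n_edges = draw(st.integers(0, 8))
    edges = []
    for _ in range(n_edges):
        scenario = draw(st.sampled_from([1, 2, 3]))
        if scenario == 3:
            regs = tuple(
                draw(st.lists(st.sampled_from(names), min_size=2, max_size=2))
            )
        else:
            regs = (draw(st.sampled_from(names)),)
        edges.append(
            EdgeSpec(
                regulators=regs,
                target=draw(st.sampled_from(names)),
                sign=draw(st.sampled_from(["activation", "inhibition"])),
                scenario=scenario,
                k=draw(
                    st.floats(0.01, 10.0, allow_nan=False, allow_infinity=False)
                ),
                reaction_class=draw(st.sampled_from(["slow", "fast"])),
            )
        )
    return NetworkModel(nodes=nodes, edges=edges, metadata={"name": "rand"})


@given(models())
@settings(max_examples=60, deadline=None)
def test_load_save_round_trip(model):
    again = loads_model(dumps_model(model))
    assert again.structurally_equal(model)


@given(models())
@settings(max_examples=40, deadline=None)
def test_validation_accepts_generated_models(model):
    model.validate()  # must not raise


def test_fixture_files_match_builders():
    for name in fixtures.MOTIF_NAMES:
        on_disk = load_model(fixtures.fixture_path(name))
        assert on_disk.structurally_equal(fixtures.motif(name)), name
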