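"""Method registry, FPS extension, dispatcher behaviour and assembly."""

import numpy as np
import pytest

from discopep.design_methods import (
    FAMILY_ALIASES,
    Part,
    assemble,
    design,
    expand_method_selection,
    get_method,
    method_names,
    registry,
)
from discopep.fixtures import FixtureSpec, collinear_spec, segmented_cloud_spec

from conftest import context_from_spec

TABLE_NAMES = [
    "FPS",
    "NN", "uNN", "FNN", "ONN", "OFN", "OPP",
    "NNala", "uNNala", "ONNala", "FNala", "OFNala", "OPPala",
    "NNsa", "ONNsa", "FNsa", "OFNsa", "OPPsa",
    "NNsas", "ONNsas", "FNsas", "OFNsas", "OPPsas",
    "SHPnat", "SHPrev", "SHPaa",
    "TSPnat1", "TSPnat2", "TSPnat3", "TSPnat4",
    "TSPrev1", "TSPrev2", "TSPrev3", "TSPrev4", "TSPaa",
]


class TestRegistry:
    def test_thirty_five_methods_one_continuous(self):
        methods = registry()
        assert len(methods) == 35
        discontinuous = [m for m in methods if m.epitope_type == "discontinuous"]
        assert len(discontinuous) == 34
        (continuous,) = [m for m in methods if m.epitope_type == "continuous"]
        assert continuous.name == "FPS"

    def test_names_match_the_published_table(self):
        assert method_names() == TABLE_NAMES
        assert len(set(method_names())) == 35

    def test_family_sizes(self):
        by_family = {}
        for m in registry():
            by_family.setdefault(m.family, []).append(m.name)
        assert len(by_family["sequential"]) == 1
        assert sorted(by_family["prime"]) == sorted(["NN", "uNN", "FNN", "ONN", "OFN", "OPP"])
        assert len(by_family["prime_ala"]) == 6
        assert len(by_family["prime_sa"]) == 5
        assert len(by_family["prime_sas"]) == 5
        assert len(by_family["shp"]) == 3
        assert len(by_family["tsp"]) == 9

    def test_lookup_is_case_insensitive(self):
        assert get_method("ofn").name == "OFN"
        assert get_method("TSPNAT3").name == "TSPnat3"
        with pytest.raises(KeyError):
            get_method("nope")

    def test_residue_level_methods(self):
        assert get_method("SHPaa").element_kind == "aa"
        assert get_method("TSPaa").element_kind == "aa"
        assert sum(m.element_kind == "aa" for m in registry()) == 2

    def test_family_alias_expansion(self):
        assert expand_method_selection(["prime"]) == list(FAMILY_ALIASES["prime"])
        assert expand_method_selection(["NN", "prime"]) == list(FAMILY_ALIASES["prime"])
        expanded = expand_method_selection(["prime", "ala", "sa"])
        assert len(expanded) == 17


@pytest.fixture(scope="module")
def chain30():
    # 30-mer, all accessible, one long segment
    return context_from_spec(collinear_spec("ACDEFGHIKLMNPQRSTVWY" "ACDEFGHIKL", spacing=6.0))


class TestFPS:
    def test_symmetric_extension(self, chain30):
        ctx = chain30
        (segment,) = ctx.segments
        # a sub-reference spanning author positions 10-14
        sub = [r for r in ctx.structure.chain("A") if 10 <= r.author_number <= 14]
        from discopep.segmentation import _make_segment
        ref = _make_segment(99, "A", sub, ctx.profile)
        pep = design("FPS", ctx, ref, 9)
        numbers = [key[1] for key in pep.provenance]
        assert numbers == list(range(8, 17))

    def test_target_not_above_reference_length(self, chain30):
        ctx = chain30
        sub = [r for r in ctx.structure.chain("A") if 10 <= r.author_number <= 14]
        from discopep.segmentation import _make_segment
        ref = _make_segment(99, "A", sub, ctx.profile)
        pep = design("FPS", ctx, ref, 3)
        assert [key[1] for key in pep.provenance] == [10, 11, 12, 13, 14]

    def test_clamped_at_chain_start(self, chain30):
        ctx = chain30
        sub = [r for r in ctx.structure.chain("A") if r.author_number <= 5]
        from discopep.segmentation import _make_segment
        ref = _make_segment(99, "A", sub, ctx.profile)
        pep = design("FPS", ctx, ref, 7)
        assert [key[1] for key in pep.provenance] == [1, 2, 3, 4, 5, 6, 7]


class TestWorkedExample:
    """Flanking selection + constrained reordering on a four-segment layout."""

    def test_ofn_assembles_the_seventeen_mer(self, worked_example_ctx):
        ctx = worked_example_ctx
        ref = next(s for s in ctx.segments if s.sequence == "YGDGDHNGLYAD")
        pep = design("OFN", ctx, ref, 17)
        assert pep.sequence == "KYGDGDHNGLYADVETR"
        assert len(pep.parts) == 4
        assert [p.sequence for p in pep.parts] == ["K", "YGDGDHNGLYAD", "V", "ETR"]
        assert pep.exact_solver
        # reference stays at the position flanking gave it
        assert pep.notes["flanking_order"].index(ref.id) == 1

    def test_fnn_matches_without_reordering(self, worked_example_ctx):
        ctx = worked_example_ctx
        ref = next(s for s in ctx.segments if s.sequence == "YGDGDHNGLYAD")
        pep = design("FNN", ctx, ref, 17)
        assert pep.sequence == "KYGDGDHNGLYADVETR"

    def test_provenance_points_into_the_structure(self, worked_example_ctx):
        ctx = worked_example_ctx
        ref = next(s for s in ctx.segments if s.sequence == "YGDGDHNGLYAD")
        pep = design("OFN", ctx, ref, 17)
        accessible = set(ctx.profile.accessible_keys())
        for key, letter in zip(pep.provenance, pep.sequence):
            assert key in accessible
            assert ctx.structure.residue(key).name1 == letter


def single_segment_ctx():
    return context_from_spec(collinear_spec("ACDEF", spacing=6.0))


@pytest.mark.parametrize("method", ["NN", "uNN", "FNN", "ONN", "OFN", "OPP",
                                    "SHPnat", "TSPnat2", "NNala", "NNsa"])
def test_area_with_only_the_reference_returns_it(method):
    ctx = single_segment_ctx()
    (segment,) = ctx.segments
    pep = design(method, ctx, segment, 10)
    assert pep.sequence == "ACDEF"
    assert pep.reference == segment.id


def test_nn_with_ala_linkers_on_collinear_gaps():
    # three single-residue segments with 7.6 A gaps -> one Ala per junction
    spec = FixtureSpec(
        name="ala-gaps",
        ca_coordinates=np.array([[0, 0, 0], [7.6, 0, 0], [15.2, 0, 0]]),
        sequence="KDE",
        author_numbers=(10, 20, 30),
    )
    ctx = context_from_spec(spec)
    ref = ctx.segments[0]
    plain = design("NN", ctx, ref, 3)
    linked = design("NNala", ctx, ref, 3)
    assert plain.sequence == "KDE"
    assert linked.sequence == "KADAE"
    assert [p.kind for p in linked.parts] == [
        "segment", "linker", "segment", "linker", "segment"
    ]
    assert linked.provenance[1] == "linker"


def test_sas_linkers_never_longer_than_sa():
    ctx = context_from_spec(segmented_cloud_spec(n_segments=5, seed=2))
    ref = ctx.segments[0]
    sa = design("NNsa", ctx, ref, 14)
    sas = design("NNsas", ctx, ref, 14)
    sa_linker = sum(len(p.sequence) for p in sa.parts if p.kind == "linker")
    sas_linker = sum(len(p.sequence) for p in sas.parts if p.kind == "linker")
    assert sas_linker <= sa_linker


@pytest.mark.parametrize("seed", range(4))
def test_optimised_variants_never_longer(seed):
    ctx = context_from_spec(segmented_cloud_spec(n_segments=6, seed=seed))
    ref = ctx.segments[0]
    nn = design("NN", ctx, ref, 14)
    onn = design("ONN", ctx, ref, 14)
    unn = design("uNN", ctx, ref, 14)
    fnn = design("FNN", ctx, ref, 14)
    ofn = design("OFN", ctx, ref, 14)
    assert sorted(p.element_id for p in onn.parts) == sorted(p.element_id for p in nn.parts)
    assert onn.total_junction_length <= nn.total_junction_length + 1e-9
    assert unn.total_junction_length <= nn.total_junction_length + 1e-9
    assert ofn.total_junction_length <= fnn.total_junction_length + 1e-9


@pytest.mark.parametrize("seed", range(3))
def test_peptide_invariants_across_methods(seed):
    ctx = context_from_spec(segmented_cloud_spec(n_segments=5, seed=10 + seed))
    ref = ctx.segments[1]
    for method in ("NN", "uNN", "FNN", "ONN", "OFN", "OPP", "SHPnat", "SHPrev",
                   "TSPnat1", "TSPnat2", "TSPnat3", "TSPnat4", "TSPrev2",
                   "NNala", "OFNsa", "SHPaa", "TSPaa"):
        pep = design(method, ctx, ref, 12)
        assert len(pep) >= 1
        non_linker = [k for k in pep.provenance if k != "linker"]
        accessible = set(ctx.profile.accessible_keys())
        assert set(non_linker) <= accessible
        if get_method(method).element_kind == "segment":
            assert len(pep) >= len(ref)
            assert any(p.element_id == ref.id for p in pep.parts)


def test_tsp_variant_selections_differ_as_documented():
    ctx = context_from_spec(segmented_cloud_spec(n_segments=7, seed=4))
    ref = ctx.segments[0]
    opts = {"area": "all"}
    full = design("TSPnat2", ctx, ref, 8, opts)
    forced = design("TSPnat4", ctx, ref, 8, opts)
    by_dist = sorted(
        (s for s in ctx.segments if s.id != ref.id),
        key=lambda s: float(np.linalg.norm(s.g_point - ref.g_point)),
    )
    closest_two = {s.id for s in by_dist[:2]}
    chosen = {p.element_id for p in forced.parts if p.kind == "segment"}
    assert closest_two <= chosen
    assert full.total_residues if hasattr(full, "total_residues") else True


def test_assemble_concatenation_and_reversal():
    def part(eid, seq, orientation="natural"):
        keys = tuple(("A", 100 + i, "") for i in range(len(seq)))
        if orientation == "reverse":
            seq = seq[::-1]
            keys = tuple(reversed(keys))
        return Part("segment", eid, orientation, seq, keys)

    parts = [part(0, "K"), part(1, "YGDGDHNGLYAD"), part(2, "V"), part(3, "ETR")]
    sequence, provenance = assemble(parts)
    assert sequence == "KYGDGDHNGLYADVETR"
    assert len(provenance) == 17

    linker = Part("linker", "ALA", "natural", "A", ())
    with_linker = parts[:1] + [linker] + parts[1:]
    sequence2, provenance2 = assemble(with_linker)
    assert len(sequence2) == len(sequence) + 1
    assert provenance2[1] == "linker"

    reversed_part = part(3, "ETR", orientation="reverse")
    assert reversed_part.sequence == "RTE"


def test_error_cases():
    ctx = single_segment_ctx()
    with pytest.raises(KeyError):
        design("not-a-method", ctx, 0, 10)
    with pytest.raises(ValueError):
        design("NN", ctx, 0, 0)
    with pytest.raises(KeyError):
        design("NN", ctx, 99, 10)
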