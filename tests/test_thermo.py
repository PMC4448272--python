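"""Unit tests of the NN motif energies and parameter tables."""

import hashlib
import math
from importlib import resources

import numpy as np
import pytest

from hairpinscan.thermo import (
    CANONICAL_PAIRS,
    Motif,
    MotifKind,
    ParameterLookupError,
    bulge_energy,
    dangling_end_energy,
    helix_energy,
    internal_loop_energy,
    long_loop_extension,
    motif_energy,
    total_energy,
)

GC = ("G", "C")
CG = ("C", "G")
AU = ("A", "U")

TABLE_SHA256 = {
    "nn_dangle.tsv": "bed8dd1a2e4a80f3aa0a98167bd899fd90fe87a60efaef392e108cfba54e9365",
    "nn_loop_init.tsv": "28ff2cd6713155f627ff138423a4585ab2630c3a34cb8963f1686694c90b3ae2",
    "nn_scalars.tsv": "bbe33c290959bab3cf7b7b95cdcb08d8ff4bcabd417d5c62a34f0c33785016e0",
    "nn_stacking.tsv": "5cd421b6634e376d3792e2b09ca4df87ad18000c53ad977e09e11e927d3cc112",
    "nn_terminal_mismatch.tsv": "7bb291ceb6662842d018d83ca1a7915c1634d889ac63e98cc75f1a007a773729",
}


def test_bundled_tables_pinned():
    for name, digest in TABLE_SHA256.items():
        data = resources.files("hairpinscan.data").joinpath(name).read_bytes()
        assert hashlib.sha256(data).hexdigest() == digest, name


def test_scalar_constants(params):
    assert params.asym_penalty == 0.6
    assert params.ru_closure == 0.7
    assert params.ru_end == 0.45
    assert params.c_bulge == -0.9
    assert params.gas_constant == 8.3144621
    assert params.temperature == 310.15
    assert params.long_loop_coeff == 1.75
    assert params.rt == pytest.approx(8.3144621 * 310.15 / 4184.0)


def test_table_completeness_and_symmetry(params):
    assert len(params.stacking) == 36
    rev = {"AU": "UA", "UA": "AU", "GC": "CG", "CG": "GC", "GU": "UG", "UG": "GU"}
    for (p1, p2), v in params.stacking.items():
        assert math.isfinite(v)
        assert params.stacking[(rev[p2], rev[p1])] == v
    for tab in (params.internal_init, params.bulge_init):
        assert set(tab) == set(range(1, 31))
        for n in range(3, 30):
            assert tab[n + 1] >= tab[n]
    assert len(params.terminal_mismatch) == 6 * 4 * 4
    assert len(params.dangle) == 6 * 4 * 2


# ---------------------------------------------------------------------------
# internal loops
# ---------------------------------------------------------------------------


def test_internal_loop_symmetric_has_no_asymmetry_term(params):
    m = Motif.internal_loop("AA", "AA", GC, GC)
    expected = (
        params.internal_init[4]
        + params.terminal_mismatch[("GC", "A", "A")] * 2
    )
    assert internal_loop_energy(params, m) == pytest.approx(expected)


def test_internal_loop_asymmetry_penalty(params):
    # same total size n=4 and identical mismatch contexts: only |n1-n2| differs
    sym = Motif.internal_loop("AA", "AA", GC, GC)
    asym = Motif.internal_loop("AAA", "A", GC, GC)
    diff = internal_loop_energy(params, asym) - internal_loop_energy(params, sym)
    assert diff == pytest.approx(0.6 * 2)


def test_internal_loop_ru_closure_term(params):
    base = Motif.internal_loop("AA", "AA", GC, GC)
    ru = Motif.internal_loop("AA", "AA", AU, GC)
    tm_diff = (
        params.terminal_mismatch[("AU", "A", "A")]
        - params.terminal_mismatch[("GC", "A", "A")]
    )
    closure = (
        internal_loop_energy(params, ru)
        - internal_loop_energy(params, base)
        - tm_diff
    )
    assert closure == pytest.approx(0.7)


def test_internal_loop_rejects_bulge_and_bad_base(params):
    with pytest.raises(ValueError):
        internal_loop_energy(params, Motif(kind=MotifKind.INTERNAL_LOOP, n1=0, n2=2,
                                           base_pairs=(GC, GC), unpaired2="AA"))
    with pytest.raises(ParameterLookupError):
        internal_loop_energy(params, Motif.internal_loop("AX", "AA", GC, GC))


# ---------------------------------------------------------------------------
# bulges
# ---------------------------------------------------------------------------


def test_bulge_n3_is_pure_initiation(params):
    m = Motif.bulge("AAA", 1, GC, CG)
    assert bulge_energy(params, m) == params.bulge_init[3]


def test_single_c_bulge_bonus(params):
    # bulged C flanked by a paired C on the same strand
    with_c = Motif.bulge("C", 1, CG, GC)
    no_c = Motif.bulge("A", 1, CG, GC)
    expected_with = (
        params.bulge_init[1]
        + params.stacking[("CG", "GC")]
        + params.c_bulge
    )
    expected_no = params.bulge_init[1] + params.stacking[("CG", "GC")]
    assert bulge_energy(params, with_c) == pytest.approx(expected_with)
    assert bulge_energy(params, no_c) == pytest.approx(expected_no)


def test_single_bulge_conformation_entropy(params):
    t1 = Motif.bulge("A", 1, GC, GC, t_conformations=1)
    t3 = Motif.bulge("A", 1, GC, GC, t_conformations=3)
    assert bulge_energy(params, t1) - bulge_energy(params, t3) == pytest.approx(
        params.rt * math.log(3)
    )


def test_bulge_rejects_degenerate(params):
    with pytest.raises(ValueError):
        bulge_energy(params, Motif(kind=MotifKind.BULGE, base_pairs=(GC, GC)))
    with pytest.raises(ValueError):
        bulge_energy(params, Motif.bulge("A", 1, GC, GC, t_conformations=0))


# ---------------------------------------------------------------------------
# long loops
# ---------------------------------------------------------------------------


def test_long_loop_continuity_at_30(params):
    limit = long_loop_extension(params, "internal", 30 + 1e-12)
    assert abs(limit - params.internal_init[30]) < 1e-9


def test_long_loop_monotone_and_bounded_domain(params):
    values = [long_loop_extension(params, "bulge", n) for n in range(31, 301)]
    assert all(b > a for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        long_loop_extension(params, "internal", 30)
    assert long_loop_extension(params, "internal", 60) == pytest.approx(
        params.internal_init[30] + 1.75 * params.rt * math.log(2.0)
    )


def test_internal_loop_beyond_table_uses_extension(params):
    m = Motif.internal_loop("A" * 20, "A" * 20, GC, GC)
    expected = (
        long_loop_extension(params, "internal", 40)
        + params.terminal_mismatch[("GC", "A", "A")] * 2
    )
    assert internal_loop_energy(params, m) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------


def _manual_stack_sum(pairs):
    """Independent hand summation straight from the shipped TSV."""
    text = resources.files("hairpinscan.data").joinpath("nn_stacking.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if line.startswith("#") or line.startswith("pair1") or not line.strip():
            continue
        p1, p2, dg = line.split("\t")
        table[(p1, p2)] = float(dg)
    keys = ["".join(p) for p in pairs]
    return sum(table[(a, b)] for a, b in zip(keys, keys[1:]))


def test_single_pair_helix_has_no_stacking(params):
    assert helix_energy(params, Motif.helix([GC])) == 0.0


def test_six_gc_helix_matches_manual_table_sum(params):
    pairs = [GC] * 6
    assert helix_energy(params, Motif.helix(pairs)) == pytest.approx(
        _manual_stack_sum(pairs)
    )


def test_au_helix_ends_cost_045_each(params):
    inner = [GC] * 4
    no_ru = helix_energy(params, Motif.helix(inner))
    with_ru = helix_energy(params, Motif.helix([AU] + inner + [AU]))
    manual = _manual_stack_sum([AU] + inner + [AU])
    assert with_ru == pytest.approx(manual + 2 * 0.45)
    assert no_ru == pytest.approx(_manual_stack_sum(inner))


def test_symmetry_correction_for_self_complementary_duplex(params):
    sym = Motif.helix([GC, CG])  # strand1 GC == strand2 read 5'->3'
    plain = Motif.helix([GC, GC])
    assert helix_energy(params, sym) == pytest.approx(
        params.stacking[("GC", "CG")] + params.sym_correction
    )
    assert helix_energy(params, plain) == pytest.approx(params.stacking[("GC", "GC")])


def test_helix_duplex_reversal_symmetry(params, rng):
    for _ in range(50):
        pairs = [tuple(CANONICAL_PAIRS[k]) for k in rng.integers(0, 6, size=6)]
        rev = [(y, x) for (x, y) in reversed(pairs)]
        m, mr = Motif.helix(pairs), Motif.helix(rev)
        s1 = "".join(p[0] for p in pairs)
        s2 = "".join(p[1] for p in reversed(pairs))
        if s1 == s2:  # self-complementary: correction applies asymmetrically
            continue
        assert helix_energy(params, m) == pytest.approx(helix_energy(params, mr))


def test_more_gc_pairs_lower_energy(params, rng):
    for _ in range(50):
        pairs = [tuple(CANONICAL_PAIRS[k]) for k in rng.integers(0, 6, size=8)]
        pos = int(rng.integers(0, 8))
        if pairs[pos] in (GC, CG):
            continue
        upgraded = list(pairs)
        upgraded[pos] = GC
        assert helix_energy(params, Motif.helix(upgraded)) < helix_energy(
            params, Motif.helix(pairs)
        )


def test_helix_rejects_non_canonical(params):
    with pytest.raises(ParameterLookupError):
        helix_energy(params, Motif.helix([GC, ("A", "G")]))


# ---------------------------------------------------------------------------
# dangles / dispatch / totals
# ---------------------------------------------------------------------------


def test_dangle_lookup_complete_and_stabilizing(params):
    for cp in CANONICAL_PAIRS:
        for b in "ACGU":
            for side in ("5", "3"):
                v = dangling_end_energy(params, tuple(cp), b, side)
                assert v <= 0.0
    with pytest.raises(ParameterLookupError):
        dangling_end_energy(params, GC, "X", "3")


def test_motif_energy_dispatch(params):
    h = Motif.helix([GC, CG])
    il = Motif.internal_loop("A", "A", GC, GC)
    b = Motif.bulge("A", 2, GC, GC)
    assert motif_energy(params, h) == helix_energy(params, h)
    assert motif_energy(params, il) == internal_loop_energy(params, il)
    assert motif_energy(params, b) == bulge_energy(params, b)


def test_total_energy_additivity_and_empty(params):
    h = Motif.helix([GC] * 3)
    il = Motif.internal_loop("AA", "A", GC, CG)
    assert total_energy(params, [h, il]) == pytest.approx(
        motif_energy(params, h) + motif_energy(params, il)
    )
    assert total_energy(params, [h, il]) == pytest.approx(
        total_energy(params, [h]) + total_energy(params, [il])
    )
    with pytest.warns(UserWarning):
        assert total_energy(params, []) == 0.0


def test_all_energies_finite_for_random_valid_motifs(params, rng):
    for _ in range(300):
        kind = rng.integers(0, 3)
        left = tuple(CANONICAL_PAIRS[rng.integers(0, 6)])
        right = tuple(CANONICAL_PAIRS[rng.integers(0, 6)])
        if kind == 0:
            k = int(rng.integers(1, 12))
            m = Motif.helix([tuple(CANONICAL_PAIRS[j]) for j in rng.integers(0, 6, k)])
        elif kind == 1:
            n1, n2 = int(rng.integers(1, 20)), int(rng.integers(1, 20))
            m = Motif.internal_loop(
                "".join(rng.choice(list("ACGU"), n1)),
                "".join(rng.choice(list("ACGU"), n2)),
                left, right,
            )
        else:
            n = int(rng.integers(1, 40))
            m = Motif.bulge("".join(rng.choice(list("ACGU"), n)),
                            int(rng.integers(1, 3)), left, right)
        assert math.isfinite(motif_energy(params, m))
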