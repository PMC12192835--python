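"""K2P divergence, resolution statistic, concatenation search."""

import itertools
import math

import numpy as np
import pytest

from oracles import k2p_closed_form

from plastobarcode import barcode
from plastobarcode.genome_io import Locus


# --- K2P ------------------------------------------------------------------


def test_identical_sequences_have_zero_distance():
    d = barcode.k2p_distance("ACGTACGT", "ACGTACGT")
    assert d.P == d.Q == 0 and d.d == 0 and d.defined


def test_k2p_one_transition_in_ten_sites():
    d = barcode.k2p_distance("A" * 9 + "G", "A" * 10)
    assert d.P == pytest.approx(0.1) and d.Q == 0
    assert d.d == pytest.approx(k2p_closed_form(0.1, 0.0))
    assert d.d == pytest.approx(0.1116, abs=5e-5)


def test_k2p_one_transversion_in_ten_sites():
    d = barcode.k2p_distance("A" * 9 + "C", "A" * 10)
    assert d.P == 0 and d.Q == pytest.approx(0.1)
    assert d.d == pytest.approx(k2p_closed_form(0.0, 0.1))
    assert d.d == pytest.approx(0.1085, abs=5e-5)


def test_k2p_small_divergence_limit_equals_p_plus_q():
    n = 10_000
    s1 = "A" * n
    s2 = "G" + "C" + "A" * (n - 2)  # one transition, one transversion
    d = barcode.k2p_distance(s1, s2)
    assert d.P == d.Q == pytest.approx(1e-4)
    assert d.d == pytest.approx(d.P + d.Q, rel=0.01)


def test_gap_and_n_sites_excluded():
    d = barcode.k2p_distance("ACG-NA", "ACGTTA")
    assert d.n_sites == 4 and d.d == 0


def test_saturated_distance_flagged_not_capped():
    d = barcode.k2p_distance("ACGT" * 5, "GTAC" * 5)
    assert not d.defined and math.isnan(d.d)


def test_no_comparable_sites_raises():
    with pytest.raises(barcode.NoComparableSites):
        barcode.k2p_distance("NNN", "AAA")


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        barcode.k2p_distance("AAA", "AAAA")


def test_k2p_matrix_agrees_with_scalar_and_is_symmetric():
    rng = np.random.default_rng(6)
    aligned = {}
    base = "".join(rng.choice(list("ACGT"), 300))
    for i in range(6):
        s = list(base)
        for p in rng.integers(0, 300, size=8):
            s[p] = str(rng.choice(list("ACGT")))
        aligned[f"a{i}"] = "".join(s)
    dm = barcode.k2p_matrix(aligned)
    labels = dm.labels
    for i, j in itertools.combinations(range(len(labels)), 2):
        scalar = barcode.k2p_distance(aligned[labels[i]], aligned[labels[j]])
        assert dm.values[i, j] == pytest.approx(scalar.d)
        assert dm.values[i, j] == dm.values[j, i]
    assert np.all(np.diag(dm.values) == 0)


# --- per-locus matrices and resolution ------------------------------------


def _locus(haps: dict[str, str], name="loc", kind="gene") -> Locus:
    return Locus(name=name, kind=kind, sequences=haps)


def test_identical_locus_gives_all_zero_matrix():
    dm = barcode.locus_distance_matrix(_locus({f"a{i}": "ACGTACGT" for i in range(5)}))
    assert np.all(dm.values == 0)


def test_single_diagnostic_snp_splits_matrix_into_two_blocks():
    haps = {f"x{i}": "AAAAAAAAAA" for i in range(3)}
    haps.update({f"y{i}": "AAAAAAAAAG" for i in range(3)})
    dm = barcode.locus_distance_matrix(_locus(haps))
    expected = barcode.k2p_distance("AAAAAAAAAA", "AAAAAAAAAG").d
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            same = a[0] == b[0]
            assert dm.values[i, j] == pytest.approx(0 if same else expected)


def test_unequal_length_locus_aligned_before_distances():
    haps = {"a": "ACGTACGTACGTACGT", "b": "ACGTACGACGTACGT", "c": "ACGTACGTACGTACGT"}
    dm = barcode.locus_distance_matrix(_locus(haps))  # b has a 1 bp deletion
    ia, ib = dm.labels.index("a"), dm.labels.index("b")
    assert dm.values[ia, ib] == 0  # indel columns excluded from K2P


def test_resolution_all_identical_and_all_distinct():
    assert barcode.resolution_from_locus(
        _locus({f"a{i}": "ACGT" for i in range(10)})
    ).resolution_pct == 0.0
    haps = {f"a{i}": "AAA" + "ACGT"[i % 4] + "ACGT"[i // 4] for i in range(10)}
    assert len(set(haps.values())) == 10
    assert barcode.resolution_from_locus(_locus(haps)).resolution_pct == 100.0


def test_resolution_granularity_on_34_accessions():
    # exactly 3 unique haplotypes among 34: 3/34 = 8.82%
    haps = {f"a{i:02d}": "AAAA" for i in range(34)}
    haps["a00"], haps["a01"], haps["a02"] = "AAAC", "AACC", "ACCC"
    r = barcode.resolution_from_locus(_locus(haps))
    assert r.resolution_pct == pytest.approx(8.82, abs=0.005)
    assert r.resolved_ids == frozenset({"a00", "a01", "a02"})


def test_resolution_score_from_matrix_matches_haplotype_route():
    haps = {f"a{i:02d}": "AAAAAAAA" for i in range(8)}
    haps["a00"] = "AAAAAAAG"
    haps["a01"] = "AAAAAAGG"
    loc = _locus(haps)
    via_matrix = barcode.resolution_score(barcode.locus_distance_matrix(loc))
    via_haps = barcode.resolution_from_locus(loc)
    assert via_matrix.resolved_ids == via_haps.resolved_ids


def test_resolution_invariant_to_accession_order():
    haps = {f"a{i}": ("ACGT" if i < 2 else "AGGT") for i in range(6)}
    r1 = barcode.resolution_from_locus(_locus(haps))
    r2 = barcode.resolution_from_locus(_locus(dict(reversed(list(haps.items())))))
    assert r1.resolved_ids == r2.resolved_ids


# --- concatenation --------------------------------------------------------


def test_self_concatenation_doubles_length_preserves_resolution():
    haps = {"a": "ACGT", "b": "ACGA", "c": "ACGT"}
    loc = _locus(haps)
    cat = barcode.concatenate_loci([loc, loc])
    assert all(len(s) == 8 for s in cat.sequences.values())
    assert (barcode.resolution_from_locus(cat).resolved_ids
            == barcode.resolution_from_locus(loc).resolved_ids)


def test_concatenation_requires_matching_accessions():
    with pytest.raises(ValueError):
        barcode.concatenate_loci(
            [_locus({"a": "AC", "b": "AC"}), _locus({"a": "AC", "c": "AC"}, name="z")]
        )


def test_complementary_loci_union_their_resolved_sets():
    l1 = _locus({"a": "AAAC", "b": "AAAA", "c": "AAAA", "d": "AAAA"}, name="l1")
    l2 = _locus({"a": "TTTT", "b": "TTTG", "c": "TTTT", "d": "TTTT"}, name="l2")
    r1 = barcode.resolution_from_locus(l1).resolved_ids
    r2 = barcode.resolution_from_locus(l2).resolved_ids
    cat = barcode.concatenate_loci([l1, l2])
    assert barcode.resolution_from_locus(cat).resolved_ids == r1 | r2


def test_adding_a_locus_never_shrinks_the_resolved_set():
    rng = np.random.default_rng(17)
    accs = [f"a{i}" for i in range(8)]
    for _ in range(60):
        k = int(rng.integers(2, 5))
        loci = []
        for t in range(k):
            haps = {a: "".join(rng.choice(list("AC"), 3)) for a in accs}
            loci.append(_locus(haps, name=f"l{t}"))
        base = barcode.resolution_from_locus(barcode.concatenate_loci(loci[:-1]))
        more = barcode.resolution_from_locus(barcode.concatenate_loci(loci))
        assert base.resolved_ids <= more.resolved_ids


# --- search ---------------------------------------------------------------


def _random_locus_panel(rng, n_loci=8, n_acc=10):
    accs = [f"a{i:02d}" for i in range(n_acc)]
    loci = []
    for t in range(n_loci):
        haps = {a: "".join(rng.choice(list("ACGT"), 4)) if rng.random() < 0.5
                else "AAAA" for a in accs}
        kind = "gene" if t % 2 == 0 else "intergene"
        loci.append(_locus(haps, name=f"l{t:02d}", kind=kind))
    return loci


def test_exhaustive_and_beam_agree_on_best(small_dataset):
    rng = np.random.default_rng(23)
    loci = _random_locus_panel(rng)
    ex = barcode.search_concatenations(loci, k_max=3, strategy="exhaustive")
    bm = barcode.search_concatenations(loci, k_max=3, strategy="beam", beam_width=10)
    assert ex.best.resolution_pct == bm.best.resolution_pct
    assert ex.best.locus_names == bm.best.locus_names


def test_all_uninformative_loci_rank_lexicographically():
    loci = [_locus({"a": "AC", "b": "AC", "c": "AC"}, name=f"l{i}") for i in range(4)]
    rep = barcode.search_concatenations(loci, k_max=2)
    assert all(r.resolution_pct == 0 for r in rep.results)
    singles = [r for r in rep.results if len(r.locus_names) == 1]
    assert [r.locus_names[0] for r in singles] == sorted(l.name for l in loci)


def test_pair_category_counts():
    loci = [
        _locus({"a": "AC", "b": "AG"}, name="g1", kind="gene"),
        _locus({"a": "AC", "b": "AC"}, name="g2", kind="gene"),
        _locus({"a": "TT", "b": "TA"}, name="i1", kind="intergene"),
    ]
    rep = barcode.search_concatenations(loci, k_max=2, strategy="exhaustive")
    assert rep.pair_counts == {
        "gene_gene": 1, "gene_intergene": 2, "intergene_intergene": 0
    }


def test_beam_at_least_as_good_as_greedy_extension():
    rng = np.random.default_rng(31)
    for _ in range(20):
        loci = _random_locus_panel(rng, n_loci=10, n_acc=12)
        rep = barcode.search_concatenations(loci, k_max=4, strategy="beam",
                                            beam_width=8, budget=100)
        # greedy: repeatedly add the single best extension
        names = {l.name: l for l in loci}
        cur: tuple[str, ...] = ()
        for _step in range(4):
            best_next = None
            for nm in names:
                if nm in cur:
                    continue
                cat = barcode.concatenate_loci([names[x] for x in cur + (nm,)])
                r = barcode.resolution_from_locus(cat)
                key = (r.resolution_pct, -len(cur) - 1)
                if best_next is None or key > best_next[0]:
                    best_next = (key, cur + (nm,))
            cur = best_next[1]
        greedy_final = barcode.resolution_from_locus(
            barcode.concatenate_loci([names[x] for x in cur])
        )
        assert rep.best.resolution_pct >= greedy_final.resolution_pct - 1e-9


# --- hypothesis properties --------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

aligned_pairs = st.integers(10, 200).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="ACGT-N", min_size=n, max_size=n),
        st.text(alphabet="ACGT-N", min_size=n, max_size=n),
    )
)


@settings(derandomize=True, max_examples=150)
@given(aligned_pairs)
def test_k2p_is_symmetric_and_zero_iff_no_substitutions(pair):
    s1, s2 = pair
    try:
        d12 = barcode.k2p_distance(s1, s2)
    except barcode.NoComparableSites:
        with pytest.raises(barcode.NoComparableSites):
            barcode.k2p_distance(s2, s1)
        return
    d21 = barcode.k2p_distance(s2, s1)
    assert (d12.s, d12.v, d12.n_sites) == (d21.s, d21.v, d21.n_sites)
    assert 0 <= d12.P + d12.Q <= 1
    if d12.defined:
        assert d12.d == pytest.approx(d21.d)
        assert (d12.d == 0) == (d12.s == 0 and d12.v == 0)
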