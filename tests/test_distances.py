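import numpy as np
import pytest

from endemix import distances
from endemix.records import OrderAlignment


def brute_force_pair(seq_a, seq_b, model):
    """Independent per-pair distance computation by direct site loops."""
    ts = tv = n = 0
    purines = {"A", "G"}
    for a, b in zip(seq_a, seq_b):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if (a in purines) == (b in purines):
                ts += 1
            else:
                tv += 1
    p = (ts + tv) / n
    if model == "p":
        return p, n
    P, Q = ts / n, tv / n
    a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
    if a1 > 0 and a2 > 0:
        return -0.5 * np.log(a1) - 0.25 * np.log(a2), n
    return p, n


class TestPairwiseDistances:
    def test_identical_sequences_zero(self):
        aln = OrderAlignment("o", ["a", "b"], ["ACGTACGT", "ACGTACGT"])
        for model in ("p", "k2p"):
            assert distances.pairwise_distances(aln, model).d[0, 1] == 0.0

    def test_single_mismatch_p_distance(self):
        aln = OrderAlignment("o", ["a", "b"], ["AAAA", "AAAT"])
        assert distances.pairwise_distances(aln, "p").d[0, 1] == pytest.approx(0.25)

    def test_k2p_closed_form(self):
        # 600 sites, 30 transitions, 12 transversions:
        # K2P = -1/2 ln(0.88) - 1/4 ln(0.96) = 0.0741221843850
        a = list("A" * 600)
        b = list("A" * 600)
        for i in range(30):
            b[i] = "G"  # transitions
        for i in range(30, 42):
            b[i] = "C"  # transversions
        aln = OrderAlignment("o", ["a", "b"], ["".join(a), "".join(b)])
        dm = distances.pairwise_distances(aln, "k2p")
        assert dm.d[0, 1] == pytest.approx(0.0741221843850, abs=1e-10)

    def test_pairwise_deletion_skips_ambiguity(self):
        aln = OrderAlignment("o", ["a", "b"], ["ACGTN-", "ACGAAC"])
        dm = distances.pairwise_distances(aln, "p")
        # only 4 comparable sites, 1 mismatch
        assert dm.comparable_sites[0, 1] == 4
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_k2p_saturation_falls_back_to_p(self, caplog):
        # all transitions at 60% divergence: 1 - 2P - Q <= 0
        a = "A" * 10
        b = "G" * 6 + "A" * 4
        aln = OrderAlignment("o", ["a", "b"], [a, b])
        with caplog.at_level("WARNING"):
            dm = distances.pairwise_distances(aln, "k2p")
        assert dm.d[0, 1] == pytest.approx(0.6)

    def test_matches_brute_force_and_p_le_k2p(self, small_community):
        order, aln = next(iter(small_community.alignments.items()))
        sub = aln.subset(aln.ids[:12])
        dp = distances.pairwise_distances(sub, "p")
        dk = distances.pairwise_distances(sub, "k2p")
        for i in range(sub.n):
            for j in range(i + 1, sub.n):
                ep, n = brute_force_pair(sub.seqs[i], sub.seqs[j], "p")
                ek, _ = brute_force_pair(sub.seqs[i], sub.seqs[j], "k2p")
                assert dp.d[i, j] == pytest.approx(ep, abs=1e-12)
                assert dk.d[i, j] == pytest.approx(ek, abs=1e-12)
                assert dp.comparable_sites[i, j] == n
                assert dp.d[i, j] <= dk.d[i, j] + 1e-12


def brute_force_species_stats(dm, assignment):
    species = sorted(set(assignment.values()))
    idx = {s: [i for i, sid in enumerate(dm.ids) if assignment[sid] == s] for s in species}
    out = {}
    for s in species:
        within = [
            dm.d[i, j] for a, i in enumerate(idx[s]) for j in idx[s][a + 1 :]
        ]
        avg_within = float(np.mean(within)) if within else None
        nn = None
        for t in species:
            if t == s:
                continue
            cross = [dm.d[i, j] for i in idx[s] for j in idx[t]]
            m = float(np.mean(cross))
            nn = m if nn is None or m < nn else nn
        out[s] = (avg_within, nn)
    return out


class TestSpeciesStats:
    def test_forced_by_definition(self):
        d = np.array(
            [[0.0, 0.01, 0.20], [0.01, 0.0, 0.20], [0.20, 0.20, 0.0]]
        )
        dm = distances.DistanceMatrix(
            ids=["a", "b", "c"], d=d, model="p", comparable_sites=np.full((3, 3), 100)
        )
        stats = distances.species_stats(dm, {"a": "s1", "b": "s1", "c": "s2"}, "o")
        by_id = {s.species_id: s for s in stats}
        assert by_id["s1"].avg_within == pytest.approx(0.01)
        assert by_id["s2"].avg_within is None
        assert by_id["s1"].nn_distance == pytest.approx(0.20)
        assert by_id["s2"].nn_distance == pytest.approx(0.20)

    def test_matches_exhaustive_oracle_random_instance(self):
        rng = np.random.default_rng(123)
        n = 15
        a = rng.random((n, n)) * 0.3
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i:02d}" for i in range(n)]
        assignment = {sid: f"sp{rng.integers(0, 4)}" for sid in ids}
        dm = distances.DistanceMatrix(
            ids=ids, d=d, model="p", comparable_sites=np.full((n, n), 100)
        )
        stats = distances.species_stats(dm, assignment, "o")
        oracle = brute_force_species_stats(dm, assignment)
        for s in stats:
            ow, onn = oracle[s.species_id]
            if ow is None:
                assert s.avg_within is None
            else:
                assert s.avg_within == pytest.approx(ow)
            assert s.nn_distance == pytest.approx(onn)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 12
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(n)]
        assignment = {sid: f"sp{i % 3}" for i, sid in enumerate(ids)}
        dm = distances.DistanceMatrix(ids, d, "p", np.full((n, n), 50))
        ref = {
            s.species_id: (s.avg_within, s.nn_distance)
            for s in distances.species_stats(dm, assignment, "o")
        }
        perm = rng.permutation(n)
        dm2 = distances.DistanceMatrix(
            [ids[i] for i in perm],
            d[np.ix_(perm, perm)],
            "p",
            np.full((n, n), 50),
        )
        got = {
            s.species_id: (s.avg_within, s.nn_distance)
            for s in distances.species_stats(dm2, assignment, "o")
        }
        for k in ref:
            for x, y in zip(ref[k], got[k]):
                assert x == pytest.approx(y)

    def test_empty_assignment_rejected(self, toy_alignment):
        dm = distances.pairwise_distances(toy_alignment)
        with pytest.raises(ValueError):
            distances.species_stats(dm, {}, "o")

    def test_generator_targets_recovered(self):
        """Sample means of within/nearest-neighbor distances sit within
        2 SE of the generator's configured targets (order-level scaling
        switched off so the targets are the exact expectations)."""
        from endemix import SimConfig, simulate_community

        cfg = SimConfig(
            n_orders=6,
            n_endemic_species=8,
            n_introduced_species=8,
            n_unknown_species=4,
            order_effect_sd=0.0,
            short_seq_fraction=0.0,
            rng_seed=17,
        )
        com = simulate_community(cfg)
        res = {"endemic": {"nn": [], "w": []}, "introduced": {"nn": [], "w": []}}
        for order, aln in com.alignments.items():
            truth = com.truth[com.truth["order"] == order]
            keep = [
                i
                for i, s in zip(aln.ids, aln.seqs)
                if len(s) - s.count("-") >= 300
            ]
            sub = aln.subset(keep)
            assign = dict(zip(truth.specimen_id, truth.true_species))
            dm = distances.pairwise_distances(sub)
            stats = distances.species_stats(
                dm, {k: v for k, v in assign.items() if k in keep}, order
            )
            type_of = dict(zip(truth.true_species, truth.true_type))
            for s in stats:
                k = type_of[s.species_id]
                if s.nn_distance is not None:
                    res[k]["nn"].append(s.nn_distance)
                if s.avg_within is not None:
                    res[k]["w"].append(s.avg_within)
        for kind, stat, target in [
            ("endemic", "nn", cfg.endemic_nn_target),
            ("introduced", "nn", cfg.introduced_nn_target),
            ("endemic", "w", cfg.within_target_endemic),
            ("introduced", "w", cfg.within_target_introduced),
        ]:
            vals = np.array(res[kind][stat])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 2 * se, (kind, stat, vals.mean(), target)
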