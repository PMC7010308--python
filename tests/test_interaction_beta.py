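import dataclasses

import numpy as np
import pytest

from woodwebs.core_data import InteractionMatrix, RearingRecord, build_networks
from woodwebs.interaction_beta import (
    interaction_beta_all_pairs,
    network_dissimilarity,
)
from woodwebs.synthetic_data import SyntheticConfig, generate_dataset

from conftest import im, random_trimmed_matrix


def from_links(links, counts=None):
    hosts = sorted({h for h, _ in links})
    beetles = sorted({b for _, b in links})
    A = np.zeros((len(hosts), len(beetles)), dtype=int)
    for k, (h, b) in enumerate(links):
        A[hosts.index(h), beetles.index(b)] = 1 if counts is None else counts[k]
    return InteractionMatrix(hosts, beetles, A)


class TestNetworkDissimilarity:
    def test_identical_networks_zero(self):
        n = from_links([("A", "x"), ("B", "y")])
        ib = network_dissimilarity(n, n)
        assert (ib.beta_WN, ib.beta_OS, ib.beta_ST) == (0.0, 0.0, 0.0)

    def test_turnover_only_example(self):
        # shared subwebs identical; y only in N1, z only in N2
        n1 = from_links([("A", "x"), ("B", "y")])
        n2 = from_links([("A", "x"), ("B", "z")])
        ib = network_dissimilarity(n1, n2)
        assert ib.beta_OS == pytest.approx(0.0)
        assert ib.beta_WN == pytest.approx(0.5)
        assert ib.beta_ST == pytest.approx(0.5)

    def test_pure_rewiring(self):
        # same species both sides, half the links swapped
        n1 = from_links([("A", "x"), ("B", "y"), ("A", "y"), ("B", "x")])
        n2 = from_links([("A", "x"), ("B", "y")])
        ib = network_dissimilarity(n1, n2)
        assert ib.beta_ST == pytest.approx(0.0)
        assert ib.beta_WN == pytest.approx(ib.beta_OS)
        assert ib.beta_WN > 0

    def test_no_shared_species_sets_os_zero(self):
        n1 = from_links([("A", "x")])
        n2 = from_links([("B", "y")])
        ib = network_dissimilarity(n1, n2)
        assert ib.beta_OS == 0.0
        assert ib.beta_ST == ib.beta_WN == 1.0

    def test_binarization_ignores_count_magnitudes(self):
        links = [("A", "x"), ("B", "y"), ("A", "y")]
        n1 = from_links(links, counts=[1, 1, 1])
        n2 = from_links(links, counts=[9, 4, 7])
        other = from_links([("A", "x"), ("B", "x")])
        a = network_dissimilarity(n1, other)
        b = network_dissimilarity(n2, other)
        assert a == dataclasses.replace(b, pair=a.pair)

    def test_additivity_on_random_pairs(self, rng):
        for _ in range(200):
            n1 = im(random_trimmed_matrix(rng, 5, 5, 2))
            n2 = im(random_trimmed_matrix(rng, 5, 5, 2))
            ib = network_dissimilarity(n1, n2)
            assert ib.beta_WN == pytest.approx(ib.beta_OS + ib.beta_ST, abs=1e-12)
            assert 0.0 <= ib.beta_WN <= 1.0

    def test_deleting_shared_link_cannot_decrease_wn(self, rng):
        for _ in range(50):
            A = random_trimmed_matrix(rng, 4, 4, 3)
            n1, n2 = im(A), im(A.copy())
            shared = sorted(n1.links() & n2.links())
            if not shared:
                continue
            h, b = shared[0]
            B = A.copy()
            B[n2.hosts.index(h), n2.beetles.index(b)] = 0
            if not ((B.sum(1) > 0).all() and (B.sum(0) > 0).all()):
                continue
            before = network_dissimilarity(n1, n2).beta_WN
            after = network_dissimilarity(n1, im(B)).beta_WN
            assert after >= before - 1e-12


class TestAllPairs:
    def test_four_treatments_six_records(self):
        records = [
            RearingRecord(t, f"h{i}", f"b{(i + k) % 3}", 1)
            for k, t in enumerate(("Rc", "Rg", "Dc", "Dg"))
            for i in range(3)
        ]
        table, summary = interaction_beta_all_pairs(build_networks(records))
        assert len(table) == 6
        assert set(summary["metric"]) == {"beta_WN", "beta_OS", "beta_ST"}

    def test_duplicated_network_contributes_zero(self):
        records = [
            RearingRecord(t, "h1", "b1", 2)
            for t in ("Rc", "Rg")
        ]
        table, _ = interaction_beta_all_pairs(build_networks(records))
        assert table.loc[0, ["beta_WN", "beta_OS", "beta_ST"]].tolist() == [0, 0, 0]

    def test_full_retention_attributes_dissimilarity_to_rewiring(self):
        # rho=1 with dense counts: every treatment realizes the same
        # species pools, so all network dissimilarity is rewiring
        cfg = SyntheticConfig(
            n_hosts={"Rc": 8, "Rg": 8, "Dc": 8, "Dg": 8},
            n_beetles={"Rc": 6, "Rg": 6, "Dc": 6, "Dg": 6},
            total_emergences=4000,
            rho=1.0,
            kappa=2.0,
            module_boost=1.0,
            host_pool=None,
            beetle_pool=None,
            seed=7,
        )
        records, _, _ = generate_dataset(cfg)
        nets = build_networks(records)
        pools = {t: (tuple(nets[t].hosts), tuple(nets[t].beetles)) for t in nets.treatments}
        assert len(set(pools.values())) == 1  # identical realized pools
        table, summary = interaction_beta_all_pairs(nets)
        mean_st = summary.set_index("metric").loc["beta_ST", "mean"]
        assert mean_st == pytest.approx(0.0, abs=1e-12)
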