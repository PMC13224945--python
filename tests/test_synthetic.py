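"""Synthetic fixture generation: determinism, structure, label accounting."""

from __future__ import annotations

from collections import Counter

import networkx as nx
import pytest

from aopnet import (
    FixtureSpec,
    FixtureSpecError,
    generate_fixture,
    read_fixture,
    write_fixture,
)
from aopnet.synthetic import FixtureBundle
from aopnet.vocab import Adjacency, Role


def spec(**kwargs):
    return FixtureSpec(**{"n_aops": 5, "events_per_aop": (4, 6), "seed": 1, **kwargs})


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        assert generate_fixture(spec(seed=7)) == generate_fixture(spec(seed=7))

    def test_same_seed_byte_identical_files(self, tmp_path):
        paths1 = write_fixture(generate_fixture(spec(seed=7)), tmp_path / "a")
        paths2 = write_fixture(generate_fixture(spec(seed=7)), tmp_path / "b")
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes()

    def test_different_seed_different_bundle(self):
        assert generate_fixture(spec(seed=1)) != generate_fixture(spec(seed=2))


class TestStructure:
    def test_requested_number_of_aops(self):
        bundle = generate_fixture(spec(n_aops=5))
        assert len(bundle.aop_ids()) == 5

    def test_share_prob_zero_means_no_shared_events(self):
        bundle = generate_fixture(spec(ke_share_prob=0.0))
        aops_per_event = Counter()
        for r in {(r.aop_id, r.event_id) for r in bundle.ke_dataset}:
            aops_per_event[r[1]] += 1
        assert max(aops_per_event.values()) == 1

    def test_share_prob_one_creates_shared_events(self):
        bundle = generate_fixture(spec(n_aops=6, ke_share_prob=1.0, seed=3))
        aops_per_event = Counter()
        for aop_id, event_id in {(r.aop_id, r.event_id) for r in bundle.ke_dataset}:
            aops_per_event[event_id] += 1
        assert max(aops_per_event.values()) > 1

    def test_referential_integrity(self):
        bundle = generate_fixture(spec(seed=11))
        known = bundle.event_ids()
        for ker in bundle.ker_table:
            assert ker.upstream_event in known and ker.downstream_event in known

    def test_every_aop_has_mie_to_ao_path(self):
        bundle = generate_fixture(spec(seed=5, ke_share_prob=0.5))
        G = nx.DiGraph(
            (k.upstream_event, k.downstream_event) for k in bundle.ker_table
        )
        roles: dict[str, dict[str, set]] = {}
        for r in bundle.ke_dataset:
            roles.setdefault(r.aop_id, {"MIE": set(), "AO": set()})
            if r.role in (Role.MIE, Role.AO):
                roles[r.aop_id][r.role.value].add(r.event_id)
        for aop_id, rs in roles.items():
            assert rs["MIE"] and rs["AO"]
            assert any(
                nx.has_path(G, m, a) for m in rs["MIE"] for a in rs["AO"]
            )

    def test_pooled_network_is_acyclic(self):
        bundle = generate_fixture(spec(n_aops=8, ke_share_prob=0.6, seed=9))
        G = nx.DiGraph(
            (k.upstream_event, k.downstream_event)
            for k in bundle.ker_table
            if k.upstream_event != k.downstream_event
        )
        assert nx.is_directed_acyclic_graph(G)

    def test_adjacency_fraction_one_means_all_adjacent(self):
        bundle = generate_fixture(spec(adjacency_fraction=1.0))
        assert all(k.adjacency is Adjacency.ADJACENT for k in bundle.ker_table)


class TestLabelAccounting:
    def test_exact_counts_hit_exactly(self):
        # 4 AOPs x 5 events -> exactly 16 backbone KERs with no skip links
        counts = {"High": 8, "Moderate": 4, "Low": 1, "Not Specified": 3}
        bundle = generate_fixture(
            spec(
                n_aops=4,
                events_per_aop=(5, 5),
                adjacency_fraction=1.0,
                evidence_counts=counts,
                quant_counts={"High": 16},
            )
        )
        from aopnet import recode_evidence

        got = Counter(recode_evidence(k.evidence_raw).value for k in bundle.ker_table)
        assert got == Counter(counts)

    def test_mismatched_exact_counts_rejected(self):
        with pytest.raises(FixtureSpecError, match="counts sum"):
            generate_fixture(
                spec(
                    n_aops=4,
                    events_per_aop=(5, 5),
                    adjacency_fraction=1.0,
                    evidence_counts={"High": 3},
                )
            )

    def test_probabilities_within_binomial_bounds(self):
        bundle = generate_fixture(
            spec(
                n_aops=30,
                events_per_aop=(6, 6),
                adjacency_fraction=1.0,
                evidence_counts={"High": 0.5, "Not Specified": 0.5},
                seed=13,
            )
        )
        from aopnet import recode_evidence

        n = len(bundle.ker_table)
        high = sum(1 for k in bundle.ker_table if recode_evidence(k.evidence_raw).value == "High")
        # 99% binomial bounds for p=0.5 (~2.58 sigma)
        sigma = (n * 0.25) ** 0.5
        assert abs(high - 0.5 * n) <= 2.58 * sigma

    def test_coverage_fractions(self):
        bundle = generate_fixture(spec(methods_coverage=0.5, kc_coverage=0.25, seed=2))
        n = len(bundle.event_ids())
        n_methods = sum(1 for t in bundle.measurement_sections.values() if t.strip())
        assert n_methods == round(0.5 * n)
        assert len(bundle.kc_table) == round(0.25 * n)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_aops": 0}, "n_aops"),
            ({"events_per_aop": (1, 5)}, "events_per_aop"),
            ({"events_per_aop": (6, 4)}, "events_per_aop"),
            ({"ke_share_prob": 1.5}, "ke_share_prob"),
            ({"adjacency_fraction": -0.1}, "adjacency_fraction"),
            ({"kc_coverage": 2.0}, "kc_coverage"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, kwargs, field):
        with pytest.raises(FixtureSpecError, match=field):
            generate_fixture(spec(**kwargs))


class TestRoundTrip:
    def test_write_then_read_recovers_bundle(self, tmp_path):
        bundle = generate_fixture(spec(seed=21))
        write_fixture(bundle, tmp_path)
        assert read_fixture(tmp_path) == bundle

    def test_aopwiki_dialect_round_trip(self, tmp_path):
        bundle = generate_fixture(spec(seed=22))
        write_fixture(bundle, tmp_path, dialect="aopwiki")
        assert read_fixture(tmp_path, dialect="aopwiki") == bundle

    def test_empty_bundle_valid_files_with_headers(self, tmp_path):
        empty = FixtureBundle(
            ke_dataset=[], ker_table=[], measurement_sections={}, kc_table={}, manifest={}
        )
        paths = write_fixture(empty, tmp_path)
        assert paths["ke"].read_text().startswith("aop_id\tevent_id")
        assert read_fixture(tmp_path) == empty

    def test_reference_fixture_round_trips_with_94_kers(self, tmp_path, reference):
        bundle, _ = reference
        write_fixture(bundle, tmp_path)
        back = read_fixture(tmp_path)
        assert len(back.ker_table) == 94
        assert back == bundle
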