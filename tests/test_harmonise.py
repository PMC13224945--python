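"""Title standardisation, merge maps, role resolution and KER remapping."""

from __future__ import annotations

import pytest

from aopnet import (
    KERRecord,
    KeyEventRecord,
    MergeMap,
    apply_merge_map,
    remap_kers,
    resolve_role,
    standardise_title,
)
from aopnet.vocab import Role


def rec(aop, event, title, role=Role.KE):
    return KeyEventRecord(aop_id=aop, event_id=event, title=title, role=role)


class TestStandardiseTitle:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("oxidative stress", "Oxidative stress"),
            ("  decrease, cardiac contractility  ", "Decrease, cardiac contractility"),
            ("hERG channel blockade", "hERG channel blockade"),
            ("mRNA decay increased", "mRNA decay increased"),
            ("Already capitalised", "Already capitalised"),
            ("(non-alpha) first letter capitalised", "(Non-alpha) first letter capitalised"),
        ],
    )
    def test_capitalisation_rules(self, raw, expected):
        assert standardise_title(raw) == expected

    def test_na_yields_drop_signal(self):
        assert standardise_title("NA") is None
        assert standardise_title("  NA  ") is None

    def test_lowercase_na_is_a_real_title(self):
        # only the literal sentinel is dropped; "na" could be a symbol
        assert standardise_title("na") == "Na"


class TestMergeMap:
    def test_injectivity_enforced(self):
        with pytest.raises(ValueError, match="two merge-map entries"):
            MergeMap([("Heart failure", ("KE1",)), ("Oxidative stress", ("KE1",))])

    def test_duplicate_canonical_title_rejected(self):
        with pytest.raises(ValueError, match="duplicate canonical"):
            MergeMap([("heart failure", ("KE1",)), ("Heart failure", ("KE2",))])

    def test_member_id_whitespace_normalised(self):
        mm = MergeMap([("Heart failure", ("KE 1964", "KE1535"))])
        assert mm.lookup() == {"KE1964": "Heart failure", "KE1535": "Heart failure"}

    def test_tsv_round_trip(self, tmp_path):
        mm = MergeMap([("Heart failure", ("KE1535", "KE1964")), ("Oxidative stress", ("KE1392",))])
        path = tmp_path / "merge.tsv"
        mm.to_tsv(path)
        assert MergeMap.from_tsv(path).entries == mm.entries


class TestApplyMergeMap:
    def test_mapped_ids_collapse_to_one_node(self):
        records = [
            rec("AOP:261", "KE1535", "Heart failure", Role.AO),
            rec("AOP:433", "KE 1964", "Sudden cardiac death", Role.AO),
        ]
        mm = MergeMap([("Heart failure", ("KE1535", "KE1964"))])
        result = apply_merge_map(records, mm)
        assert set(result.roster) == {"Heart failure"}
        node = result.roster["Heart failure"]
        assert node.member_ids == {"KE1535", "KE1964"}
        assert node.aop_membership == {"AOP:261", "AOP:433"}

    def test_unmapped_ids_become_singleton_nodes(self):
        records = [rec("AOP:1", "KE1", "oxidative stress"), rec("AOP:1", "KE2", "Hypoxia")]
        result = apply_merge_map(records)
        assert set(result.roster) == {"Oxidative stress", "Hypoxia"}

    def test_title_collision_auto_merges_with_warning(self):
        records = [rec("AOP:1", "KE1", "hypoxia"), rec("AOP:2", "KE2", "Hypoxia")]
        result = apply_merge_map(records)
        assert result.roster["Hypoxia"].member_ids == {"KE1", "KE2"}
        assert any("auto-merged" in w for w in result.warnings)

    def test_na_titles_dropped_and_reported(self):
        records = [rec("AOP:1", "KE1", "NA"), rec("AOP:1", "KE2", "Hypoxia")]
        result = apply_merge_map(records)
        assert set(result.roster) == {"Hypoxia"}
        assert [r.event_id for r in result.dropped] == ["KE1"]

    def test_unknown_merge_map_ids_warned_not_fatal(self):
        result = apply_merge_map(
            [rec("AOP:1", "KE1", "Hypoxia")],
            MergeMap([("Ghost node", ("KE999",))]),
        )
        assert any("KE999" in w for w in result.warnings)
        assert set(result.roster) == {"Hypoxia"}

    def test_member_conservation(self):
        records = [
            rec("AOP:1", "KE1", "A"), rec("AOP:2", "KE1", "A"),
            rec("AOP:1", "KE2", "B"), rec("AOP:2", "KE3", "C"),
        ]
        result = apply_merge_map(records, MergeMap([("AB", ("KE1", "KE2"))]))
        total_members = sum(len(n.member_ids) for n in result.roster.values())
        assert total_members == 3  # distinct surviving event ids

    def test_idempotence(self):
        """Harmonising an already-harmonised roster is the identity."""
        records = [
            rec("AOP:1", "KE1", "oxidative stress"),
            rec("AOP:2", "KE2", "Increase, oxidative stress"),
            rec("AOP:2", "KE3", "Hypoxia", Role.AO),
        ]
        mm = MergeMap([("Oxidative stress", ("KE1", "KE2"))])
        first = apply_merge_map(records, mm)
        rederived = [
            KeyEventRecord(aop_id=aop, event_id=member, title=node.canonical_title, role=node.role)
            for node in first.roster.values()
            for member in sorted(node.member_ids)
            for aop in sorted(node.aop_membership)
        ]
        second = apply_merge_map(rederived, mm)
        assert second.roster == first.roster


class TestResolveRole:
    @pytest.mark.parametrize(
        "roles,expected",
        [
            ([Role.AO, Role.KE, Role.KE], Role.AO),
            ([Role.KE], Role.KE),
            ([Role.MIE, Role.KE], Role.MIE),
            ([Role.AO, Role.MIE], Role.AO),
        ],
    )
    def test_precedence_ao_over_mie_over_ke(self, roles, expected):
        assert resolve_role(roles) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_role([])


class TestRemapKers:
    def test_merged_endpoints_become_retained_self_loop(self):
        records = [
            rec("AOP:261", "KE1535", "Heart failure", Role.AO),
            rec("AOP:433", "KE1964", "Sudden cardiac death", Role.AO),
        ]
        mm = MergeMap([("Heart failure", ("KE1535", "KE1964"))])
        harmonised = apply_merge_map(records, mm)
        kers = [
            KERRecord(
                upstream_event="KE1535", downstream_event="KE1964",
                adjacency="adjacent", evidence_raw="High", quant_raw="NA",
                aop_id="AOP:261",
            )
        ]
        remapped = remap_kers(kers, harmonised)
        assert remapped.edges == [("Heart failure", "Heart failure", kers[0])]

    def test_unresolved_endpoints_reported(self):
        harmonised = apply_merge_map([rec("AOP:1", "KE1", "Hypoxia")])
        ker = KERRecord(
            upstream_event="KE1", downstream_event="KE404",
            adjacency="adjacent", evidence_raw="High", quant_raw="NA", aop_id="AOP:1",
        )
        remapped = remap_kers([ker], harmonised)
        assert remapped.edges == [] and remapped.unresolved == [ker]


def test_reference_fixture_harmonises_71_ids_to_64_nodes(reference):
    bundle, network = reference
    assert len({r.event_id for r in bundle.ke_dataset}) == 71
    assert network.n_nodes == 64
    assert network.self_loops() == ["Mitochondrial dysfunction", "Oxidative stress"]
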