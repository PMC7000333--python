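"""Drug-target prioritization cascade tests with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from pkdrx import cascade as casc
from pkdrx import simulate as sim


def _records(rows):
    return pd.DataFrame(rows, columns=casc.RECORD_COLUMNS)


def _rec(cpd, tgt, org="Homo sapiens", pchembl=6.0, conf=9, assay="A1"):
    return {
        "compound_id": cpd, "target_id": tgt, "target_organism": org,
        "pchembl": pchembl, "confidence_score": conf, "assay_id": assay,
    }


def _compounds(rows):
    return pd.DataFrame(rows, columns=["compound_id", "name", "max_phase", "atc_codes", "moa"])


def _cpd(cid, phase=4, atc=(), moa=()):
    return {"compound_id": cid, "name": cid, "max_phase": phase,
            "atc_codes": list(atc), "moa": list(moa)}


class TestQualityFilter:
    def test_measurement_boundary_thirty_keeps_twentynine_drops(self):
        rows = [_rec(f"c{i}", "T30", assay=f"a{i}") for i in range(30)]
        rows += [_rec(f"c{i}", "T29", assay=f"b{i}") for i in range(29)]
        out, rep = casc.quality_filter(_records(rows))
        assert set(out["target_id"]) == {"T30"}
        assert "T29" in rep.removed_targets

    def test_confidence_below_nine_removed(self):
        rows = [_rec(f"c{i}", "T", conf=8, assay=f"a{i}") for i in range(40)]
        out, _ = casc.quality_filter(_records(rows))
        assert out.empty

    def test_absent_pchembl_removed(self):
        rows = [_rec(f"c{i}", "T", pchembl=np.nan, assay=f"a{i}") for i in range(40)]
        out, _ = casc.quality_filter(_records(rows))
        assert out.empty

    def test_non_human_removed(self):
        rows = [_rec(f"c{i}", "T", org="Rattus norvegicus", assay=f"a{i}") for i in range(40)]
        out, _ = casc.quality_filter(_records(rows))
        assert out.empty

    def test_fixture_matches_brute_force_refilter(self):
        rng = np.random.default_rng(0)
        rows = []
        for t in range(10):
            n = int(rng.integers(10, 60))
            conf = 9 if t % 3 else 8
            org = "Homo sapiens" if t % 4 else "Mus musculus"
            for i in range(n):
                rows.append(_rec(f"c{t}_{i}", f"T{t}", org=org, conf=conf, assay=f"a{t}_{i}"))
        rec = _records(rows)
        out, _ = casc.quality_filter(rec)
        # brute force in test code
        ok = rec[(rec.confidence_score == 9) & rec.pchembl.notna()
                 & (rec.target_organism == "Homo sapiens")]
        expect = {t for t, n in ok.groupby("target_id").size().items() if n >= 30}
        assert set(out["target_id"]) == expect

    def test_malformed_record_reports_row(self):
        rec = _records([_rec("c", "T")])
        rec.loc[0, "target_id"] = None
        with pytest.raises(casc.CascadeError, match="row"):
            casc.quality_filter(rec)


class TestOrthologs:
    MAP = pd.DataFrame(
        {"mouse_id": ["Trp53", "Birc2", "Dup", "Dup"],
         "human_symbol": ["TP53", "BIRC2", "DUPA", "DUPB"]}
    )

    def _mouse(self, genes):
        return pd.DataFrame(
            [{"gene": g, "stage": "early", "direction": "up"} for g in genes]
        )

    def test_annotation_transferred(self):
        human, log = casc.map_orthologs(self._mouse(["Trp53"]), self.MAP)
        assert human.iloc[0]["gene"] == "TP53"
        assert human.iloc[0]["direction"] == "up"
        assert log.empty

    def test_unmapped_logged(self):
        human, log = casc.map_orthologs(self._mouse(["Nope"]), self.MAP)
        assert human.empty
        assert log.iloc[0].tolist() == ["Nope", "unmapped"]

    def test_multi_mapped_dropped(self):
        human, log = casc.map_orthologs(self._mouse(["Dup", "Birc2"]), self.MAP)
        assert list(human["gene"]) == ["BIRC2"]
        assert log.iloc[0].tolist() == ["Dup", "multi-mapped"]

    def test_empty_map_rejected(self):
        with pytest.raises(casc.CascadeError, match="empty"):
            casc.map_orthologs(self._mouse(["Trp53"]), pd.DataFrame(columns=["mouse_id", "human_symbol"]))


class TestPerStepFilters:
    def test_intersect_disjoint_empty_with_report(self):
        rec = _records([_rec("c", "T")])
        out, rep = casc.intersect_targets(rec, {"OTHER"})
        assert out.empty
        assert rep.removed_targets == ["T"]

    def test_phase_boundary(self):
        rec = _records([_rec("c4", "T"), _rec("c1", "T"), _rec("cx", "T")])
        cpds = _compounds([_cpd("c4", phase=4), _cpd("c1", phase=1)])  # cx unannotated
        out, _ = casc.phase_filter(rec, cpds)
        assert set(out["compound_id"]) == {"c4"}

    def test_atc_prefix_rule(self):
        rec = _records([_rec("l01", "T"), _rec("m01", "T"), _rec("both", "T"), _rec("none", "T")])
        cpds = _compounds([
            _cpd("l01", atc=["L01XX01"]),
            _cpd("m01", atc=["M01AG"]),          # meclofenamic-acid-like: kept
            _cpd("both", atc=["L01AA", "M01AG"]),  # any-match: dropped
            _cpd("none", atc=[]),
        ])
        out, rep = casc.atc_filter(rec, cpds)
        assert set(out["compound_id"]) == {"m01", "none"}
        assert sorted(rep.removed_compounds) == ["both", "l01"]

    def test_invalid_atc_code_warned_and_ignored(self):
        rec = _records([_rec("c", "T")])
        cpds = _compounds([_cpd("c", atc=["not-a-code"])])
        with pytest.warns(UserWarning, match="invalid ATC"):
            out, _ = casc.atc_filter(rec, cpds)
        assert len(out) == 1

    def test_moa_conflict_rules(self):
        rec = _records([_rec("ago", "UP"), _rec("anta", "UP"), _rec("unk", "UP"),
                        _rec("inh", "DOWN")])
        cpds = _compounds([
            _cpd("ago", moa=[("UP", "agonist")]),     # aggravates: dropped
            _cpd("anta", moa=[("UP", "antagonist")]),  # corrective: kept
            _cpd("unk"),                               # no known action: kept
            _cpd("inh", moa=[("DOWN", "inhibitor")]),  # aggravates: dropped
        ])
        out, _ = casc.moa_filter(rec, cpds, {"UP": "up", "DOWN": "down"})
        assert set(out["compound_id"]) == {"anta", "unk"}

    def test_unknown_action_vocabulary_rejected(self):
        rec = _records([_rec("c", "T")])
        cpds = _compounds([_cpd("c", moa=[("T", "blocker-ish")])])
        with pytest.raises(casc.CascadeError, match="blocker-ish"):
            casc.moa_filter(rec, cpds, {"T": "up"})

    def test_phase_and_atc_commute(self):
        rec = _records([_rec(c, "T") for c in ("a", "b", "c", "d")])
        cpds = _compounds([
            _cpd("a", phase=4, atc=["L01AA"]),
            _cpd("b", phase=1, atc=["M01AG"]),
            _cpd("c", phase=3, atc=["M01AG"]),
            _cpd("d", phase=0, atc=["L01XX"]),
        ])
        r1, _ = casc.phase_filter(rec, cpds)
        r1, _ = casc.atc_filter(r1, cpds)
        r2, _ = casc.atc_filter(rec, cpds)
        r2, _ = casc.phase_filter(r2, cpds)
        assert r1.reset_index(drop=True).equals(r2.reset_index(drop=True))


class TestStagePrioritize:
    INFO = pd.DataFrame(
        [{"gene": "EARLY", "stage": "early", "direction": "up"},
         {"gene": "ADV", "stage": "advanced", "direction": "down"},
         {"gene": "MOD", "stage": "moderate", "direction": "up"}]
    )

    def test_early_precedes_advanced(self):
        rec = _records([_rec("c1", "ADV", pchembl=9.0), _rec("c2", "EARLY", pchembl=5.0)])
        final = casc.stage_prioritize(rec, self.INFO)
        assert list(final["target"]) == ["EARLY", "ADV"]
        assert list(final["priority"]) == [1, 3]

    def test_within_tier_sorted_by_best_pchembl(self):
        rec = _records([
            _rec("c1", "EARLY", pchembl=5.0),
            _rec("c2", "MOD", pchembl=8.0),
            _rec("c3", "MOD2", pchembl=6.0),
        ])
        info = pd.concat([self.INFO, pd.DataFrame([{"gene": "MOD2", "stage": "moderate", "direction": "up"}])])
        final = casc.stage_prioritize(rec, info)
        assert list(final["target"]) == ["EARLY", "MOD", "MOD2"]

    def test_missing_stage_rejected(self):
        rec = _records([_rec("c", "UNKNOWN")])
        with pytest.raises(casc.CascadeError, match="stage"):
            casc.stage_prioritize(rec, self.INFO)


class TestPchembl:
    @pytest.mark.parametrize(
        "conc_um, expected",
        [(100.0, 4.0), (1e-3, 9.0), (1e6, 0.0)],  # 100 uM, 1 nM, 1 M
    )
    def test_known_values(self, conc_um, expected):
        assert casc.pchembl_from_concentration(conc_um) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(casc.CascadeError, match="positive"):
            casc.pchembl_from_concentration(0.0)

    def test_roundtrip_identity(self):
        for v in (4.0, 5.5, 9.1):
            back = casc.pchembl_from_concentration(casc.concentration_from_pchembl(v))
            assert back == pytest.approx(v, abs=1e-12)


class TestRunCascade:
    def _inputs(self, exact_cohort, exact_db):
        _, _, truth0 = exact_cohort
        bio, cpds, ortho, truth = exact_db
        mouse_prog = truth.progression[["gene", "stage", "direction"]]
        return bio, cpds, mouse_prog, ortho, truth.normalized_genes, truth

    def test_planted_fixture_reproduces_survivor_sets(self, exact_cohort, exact_db):
        bio, cpds, prog, ortho, norm, truth = self._inputs(exact_cohort, exact_db)
        res = casc.run_cascade(bio, cpds, prog, ortho, norm)
        by_step = {s.name: s for s in res.steps}
        for step, expect in truth.cascade_survivors.items():
            if step in ("final", "orthologs"):
                continue
            got = res.records if step == "moa" else None
            assert by_step[step].n_targets == len(expect["targets"]), step
            assert by_step[step].n_compounds == len(expect["compounds"]), step
        assert set(res.final["target"]) == truth.cascade_survivors["final"]["targets"]
        assert set(res.records["compound_id"]) == truth.cascade_survivors["final"]["compounds"]

    def test_survivor_sets_monotonically_nested(self, exact_cohort, exact_db):
        bio, cpds, prog, ortho, norm, _ = self._inputs(exact_cohort, exact_db)
        res = casc.run_cascade(bio, cpds, prog, ortho, norm)
        for prev, cur in zip(res.steps, res.steps[1:]):
            assert cur.n_targets <= prev.n_targets
            assert cur.n_compounds <= prev.n_compounds

    def test_row_order_invariance(self, exact_cohort, exact_db):
        bio, cpds, prog, ortho, norm, _ = self._inputs(exact_cohort, exact_db)
        res1 = casc.run_cascade(bio, cpds, prog, ortho, norm)
        shuffled = bio.sample(frac=1.0, random_state=3).reset_index(drop=True)
        res2 = casc.run_cascade(shuffled, cpds, prog, ortho, norm)
        assert res1.final.equals(res2.final)
        assert [s.to_dict() for s in res1.steps] == [s.to_dict() for s in res2.steps]

    def test_disabling_atc_yields_superset(self, exact_cohort, exact_db):
        bio, cpds, prog, ortho, norm, _ = self._inputs(exact_cohort, exact_db)
        with_atc = casc.run_cascade(bio, cpds, prog, ortho, norm)
        without = casc.run_cascade(bio, cpds, prog, ortho, norm, excluded_prefixes=())
        assert set(with_atc.final["target"]) <= set(without.final["target"])
        assert set(with_atc.records["compound_id"]) <= set(without.records["compound_id"])

    def test_every_removed_item_appears_in_exactly_one_step(self, exact_cohort, exact_db):
        bio, cpds, prog, ortho, norm, _ = self._inputs(exact_cohort, exact_db)
        res = casc.run_cascade(bio, cpds, prog, ortho, norm)
        seen = {}
        for step in res.steps:
            for t in step.removed_targets:
                assert t not in seen, f"target {t} removed twice"
                seen[t] = step.name
        survivors = set(res.records["target_id"])
        all_targets = set(bio["target_id"])
        assert set(seen) | survivors == all_targets

    def test_all_phase_one_compounds_empty_cascade_with_step_report(self):
        rows = [_rec(f"c{i}", "T", assay=f"a{i}") for i in range(30)]
        cpds = _compounds([_cpd(f"c{i}", phase=1) for i in range(30)])
        prog = pd.DataFrame([{"gene": "Tt", "stage": "early", "direction": "up"}])
        ortho = pd.DataFrame({"mouse_id": ["Tt"], "human_symbol": ["T"]})
        res = casc.run_cascade(_records(rows), cpds, prog, ortho, {"Tt"})
        assert res.final.empty
        by_step = {s.name: s for s in res.steps}
        assert by_step["intersect"].n_targets == 1   # still alive before phase
        assert by_step["phase"].n_targets == 0       # emptied exactly here


class TestCategorization:
    def test_prioritized_panel_has_21_other(self):
        panel = casc.load_prioritized_target_panel()
        counts = casc.categorize_targets(panel)
        assert len(panel) == 29
        assert counts["Other"] == 21
        assert counts["Protein kinases"] == 3
        assert counts["Transcription factors"] == 3
        assert counts["Cytokines and growth factors/receptors"] == 2
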