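import numpy as np
import pytest

import evostrain as es
from evostrain.errors import ConfigurationError, DomainError, FormatError, InfeasibleModelError
from evostrain.model import MetabolicModel, gpr_eval, gpr_genes
from evostrain.model_io import read_reference_fluxes
from evostrain.phenotype import fba, fva


def _mini_model(reactions, objective):
    """Assemble a MetabolicModel from (id, stoich, bounds, gpr, subsystem, comp)."""
    mets, comps = [], {}
    for _, stoich, *_rest, comp_map in reactions:
        for m in stoich:
            if m not in mets:
                mets.append(m)
                comps[m] = comp_map.get(m, "c")
    S = np.zeros((len(mets), len(reactions)))
    for j, (_, stoich, *_r) in enumerate(reactions):
        for m, c in stoich.items():
            S[mets.index(m), j] = c
    genes = []
    for *_h, gpr, _sub, _c in reactions:
        for g in gpr_genes(gpr):
            if g not in genes:
                genes.append(g)
    return MetabolicModel(
        metabolites=mets,
        reactions=[r[0] for r in reactions],
        S=S,
        lb=np.array([r[2][0] for r in reactions], float),
        ub=np.array([r[2][1] for r in reactions], float),
        objective_reaction=objective,
        gpr=[r[3] for r in reactions],
        subsystem=[r[4] for r in reactions],
        met_compartment=[comps[m] for m in mets],
        gene_ids=genes,
    )


class TestSBML:
    def test_round_trip_preserves_model(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        es.write_sbml(toy_model, path)
        back = es.read_sbml(path)
        assert back.reactions == toy_model.reactions
        assert back.metabolites == toy_model.metabolites
        np.testing.assert_allclose(back.S, toy_model.S)
        np.testing.assert_allclose(back.lb, toy_model.lb)
        np.testing.assert_allclose(back.ub, toy_model.ub)
        assert back.objective_reaction == toy_model.objective_reaction
        assert back.subsystem == toy_model.subsystem
        # GPR strings may be re-parenthesised; compare truth tables instead
        for rule_a, rule_b in zip(toy_model.gpr, back.gpr):
            genes = gpr_genes(rule_a)
            assert set(genes) == set(gpr_genes(rule_b))
            for g in genes:
                assert gpr_eval(rule_a, {g}) == gpr_eval(rule_b, {g})

    def test_legacy_l2_bounds_read(self, l2_path):
        m = es.read_sbml(l2_path)
        assert m.reactions == ["EX_A", "CONV", "BIO"]
        np.testing.assert_allclose(m.lb, [-10.0, 0.0, 0.0])
        assert m.objective_reaction == "BIO"
        assert m.gpr[1] == "gC1 and gC2"

    def test_missing_and_unparseable_files(self, tmp_path):
        with pytest.raises(FormatError):
            es.read_sbml(tmp_path / "nope.xml")
        junk = tmp_path / "junk.xml"
        junk.write_text("this is not sbml")
        with pytest.raises(FormatError):
            es.read_sbml(junk)

    def test_objective_requirement(self, toy_model, tmp_path):
        databank = es.make_databank(toy_model)
        path = tmp_path / "db.xml"
        es.write_sbml(databank, path)
        with pytest.raises(ConfigurationError):
            es.read_sbml(path)
        m = es.read_sbml(path, require_objective=False)
        assert m.objective_reaction is None
        assert m.reactions == databank.reactions

    def test_reference_flux_csv_round_trip(self, toy_model, toy_reference, tmp_path):
        import pandas as pd
        path = tmp_path / "ref.csv"
        pd.DataFrame({
            "reaction_id": list(toy_reference.fluxes),
            "flux": list(toy_reference.fluxes.values()),
        }).to_csv(path, index=False)
        back = read_reference_fluxes(path)
        np.testing.assert_allclose(back.vector(toy_model),
                                   toy_reference.vector(toy_model))


class TestCompression:
    def test_dead_end_chain_removed_other_ranges_unchanged(self, toy_model):
        chained = toy_model.copy()
        n0 = chained.n_reactions
        S = np.zeros((chained.n_metabolites + 2, n0 + 2))
        S[:chained.n_metabolites, :n0] = chained.S
        ipyr = chained.met_index("pyr")
        # DEAD1: pyr -> x1 ; DEAD2: x1 -> x2 (x2 has no consumer)
        S[ipyr, n0] = -1; S[-2, n0] = 1
        S[-2, n0 + 1] = -1; S[-1, n0 + 1] = 1
        model = MetabolicModel(
            metabolites=chained.metabolites + ["x1", "x2"],
            reactions=chained.reactions + ["DEAD1", "DEAD2"],
            S=S,
            lb=np.append(chained.lb, [0.0, 0.0]),
            ub=np.append(chained.ub, [1000.0, 1000.0]),
            objective_reaction=chained.objective_reaction,
            gpr=chained.gpr + ["gD1", "gD2"],
            subsystem=chained.subsystem + ["", ""],
            met_compartment=chained.met_compartment + ["c", "c"],
            gene_ids=chained.gene_ids + ["gD1", "gD2"],
        )
        before_min, before_max = fva(toy_model)
        compressed = es.compress_model(model)
        assert set(compressed.reactions) == set(toy_model.reactions)
        after_min, after_max = fva(compressed)
        order = [compressed.reactions.index(r) for r in toy_model.reactions]
        np.testing.assert_allclose(after_min[order], before_min, atol=1e-6)
        np.testing.assert_allclose(after_max[order], before_max, atol=1e-6)

    def test_fixed_point_and_objective_conservation(self, toy_model):
        compressed = es.compress_model(toy_model)
        assert compressed.reactions == toy_model.reactions
        again = es.compress_model(compressed)
        assert again.reactions == compressed.reactions
        _, mu0, _ = fba(toy_model)
        _, mu1, _ = fba(compressed)
        assert abs(mu0 - mu1) < 1e-9

    def test_infeasible_model_rejected(self, toy_model):
        dead = toy_model.with_bounds({r: (0.0, 0.0) for r in toy_model.reactions})
        with pytest.raises(InfeasibleModelError):
            es.compress_model(dead)


class TestLumping:
    def test_and_pair_lumped_or_pair_not(self, toy_model):
        lumped = es.lump_genes(toy_model)
        assert lumped.gene_groups == {"gA1__gA2": ("gA1", "gA2")}
        assert "gA1__gA2" in lumped.gene_ids
        assert "gA1" not in lumped.gene_ids
        # the OR isozymes of PROD survive individually
        assert {"gP1", "gP2"} <= set(lumped.gene_ids)

    def test_gene_reused_elsewhere_not_lumped(self):
        reactions = [
            ("R1", {"a": -1, "b": 1}, (0, 10), "g1 and g2", "", {}),
            ("R2", {"b": -1, "c": 1}, (0, 10), "g1", "", {}),
            ("EX_a", {"a": 1}, (0, 10), "", "", {}),
            ("EX_c", {"c": -1}, (0, 10), "", "", {}),
        ]
        m = _mini_model(reactions, "EX_c")
        lumped = es.lump_genes(m)
        assert lumped.gene_groups == {}

    def test_truth_tables_preserved_for_unit_knockouts(self, toy_model):
        """Whole-unit knockouts silence exactly the same reactions as before."""
        import itertools
        lumped = es.lump_genes(toy_model)
        units = lumped.gene_ids
        for r in range(3):
            for combo in itertools.combinations(units, r):
                silenced_new = es.reactions_silenced_by(lumped, combo)
                genes = lumped.expand_gene_units(combo)
                silenced_old = es.reactions_silenced_by(toy_model, genes)
                assert silenced_new == silenced_old


class TestTargetSpace:
    def test_stated_filter_counts(self):
        reactions = [
            ("EX_s", {"s": 1}, (-10, 0), "", "", {}),
            ("EX_p", {"p_e": -1}, (0, 10), "", "", {"p_e": "e"}),
            ("TRANS", {"p": -1, "p_e": 1}, (0, 10), "gT", "", {"p_e": "e"}),
            ("R1", {"s": -1, "p": 1}, (0, 10), "g1", "", {}),
            ("R2", {"s": -1, "p": 1}, (0, 10), "g2", "", {}),
            ("R3", {"s": -1, "p": 1}, (0, 10), "g3", "", {}),
            ("R4", {"s": -1, "p": 1}, (0, 10), "g4", "", {}),
            ("R5", {"s": -1, "p": 1}, (0, 10), "g5", "", {}),
        ]
        m = _mini_model(reactions, "R1")
        space = es.build_target_space(m)
        # 2 exchanges and the transporter are excluded; the objective R1 is
        # not a deletion target either
        assert space.deletion_targets == ["R2", "R3", "R4", "R5"]

    def test_toy_reaction_targets(self, toy_model, toy_space):
        assert toy_space.NT == 12
        assert "EX_glc" not in toy_space.deletion_targets      # exchange
        assert "T_prod" not in toy_space.deletion_targets      # transport
        assert "LIPID" not in toy_space.deletion_targets       # excluded subsystem
        assert "BIOM" not in toy_space.deletion_targets        # no gene
        assert set(toy_space.deletion_targets) <= set(toy_model.reactions)

    def test_gene_mode_targets_are_units(self, toy_model):
        lumped = es.lump_genes(toy_model)
        space = es.build_target_space(lumped, mode="gene")
        assert "gA1__gA2" in space.deletion_targets
        assert "gT" not in space.deletion_targets   # only on the transporter
        assert "gL" not in space.deletion_targets   # only in an excluded subsystem
        assert space.NT == 13

    def test_subsystem_filter_and_determinism(self, toy_model):
        narrowed = es.build_target_space(
            toy_model,
            excluded_subsystems=("membrane lipid metabolism", "overflow"))
        assert not any(t.startswith("BYP") for t in narrowed.deletion_targets)
        again = es.build_target_space(toy_model)
        assert again.deletion_targets == es.build_target_space(toy_model).deletion_targets

    def test_empty_space_rejected(self, toy_model):
        with pytest.raises(ConfigurationError):
            es.build_target_space(
                toy_model,
                extra_excluded_reactions=tuple(toy_model.reactions))


class TestMergeDatabank:
    def test_native_candidates_accepted(self, toy_model, merged_with_databank):
        merged, space = merged_with_databank
        assert space.insertion_targets == ["INS_prodx", "INS_resp", "INS_ovf"]
        assert space.NT == 12  # insertion candidates are not deletion targets

    def test_foreign_metabolite_rejected_not_fatal(self, toy_model):
        reactions = [
            ("INS_ok", {"pyr": -1, "by1": 1}, (0, 10), "gZ1", "", {}),
            ("INS_foreign", {"pyr": -1, "unobtainium": 1}, (0, 10), "gZ2", "", {}),
            ("INS_ok2", {"nadh": -1, "nad": 1}, (0, 10), "gZ3", "", {}),
        ]
        db = _mini_model(reactions, None)
        merged, space = es.merge_databank(toy_model, db)
        assert space.insertion_targets == ["INS_ok", "INS_ok2"]

    def test_inserted_reactions_closed_until_selected(self, merged_with_databank):
        merged, space = merged_with_databank
        vmin, vmax = fva(merged, space.insertion_targets)
        np.testing.assert_allclose(vmin, 0.0, atol=1e-9)
        np.testing.assert_allclose(vmax, 0.0, atol=1e-9)
        for rid in space.insertion_targets:
            lo, hi = space.insertion_bounds[rid]
            assert hi > 0

    def test_id_collision_rejected(self, toy_model):
        with pytest.raises(ConfigurationError):
            es.merge_databank(toy_model, toy_model)


def test_invalid_bounds_rejected():
    with pytest.raises(ConfigurationError):
        MetabolicModel(
            metabolites=["a"], reactions=["r"], S=np.array([[1.0]]),
            lb=np.array([1.0]), ub=np.array([-1.0]), objective_reaction="r",
            gpr=[""], subsystem=[""], met_compartment=["c"], gene_ids=[],
        )
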