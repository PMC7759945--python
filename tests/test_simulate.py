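"""Synthetic community generator: occupancy structure, detection process,
and the bundled study replica."""

import numpy as np
import pandas as pd
import pytest

from dielcam._util import TWO_PI
from dielcam.cooccur import cooccurrence_test
from dielcam.density import hermans_rasson_test
from dielcam.events import filter_independent_events
from dielcam.simulate import (
    SimulationConfig,
    SpeciesProfile,
    mixture_density,
    sample_mixture,
    simulate_detections,
    simulate_occupancy,
    study_replica_config,
    with_seed,
)
from dielcam import duikerdata


def small_config(**overrides) -> SimulationConfig:
    species = (
        SpeciesProfile("day", ((12.0, 4.0, 1.0),), 0.2, 0.5),
        SpeciesProfile("night", ((0.0, 3.0, 1.0),), 0.15, 0.4),
    )
    kw = dict(
        n_sites=2,
        stations_per_site=25,
        days_per_station=30,
        species=species,
        association=np.ones((2, 2)),
        seed=11,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


class TestProfileValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="weights"):
            SpeciesProfile("x", ((0.0, 1.0, 0.5),), 0.1, 0.5)

    def test_association_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            small_config(association=np.array([[1.0, 2.0], [3.0, 1.0]]))
        with pytest.raises(ValueError, match="positive"):
            small_config(association=np.array([[1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="seed"):
            small_config(seed=None)


class TestMixtureSampling:
    @pytest.mark.parametrize("stratified", [False, True])
    def test_marginal_law_preserved(self, rng, stratified):
        comps = ((7.0, 4.0, 0.6), (17.0, 3.0, 0.4))
        t = sample_mixture(comps, 4000, rng, stratified=stratified)
        grid = np.linspace(0, TWO_PI, 2048, endpoint=False)
        pdf = mixture_density(comps, grid)
        cdf = np.cumsum(pdf) * (TWO_PI / grid.size)
        emp = np.searchsorted(np.sort(t), grid, side="right") / t.size
        tol = 0.01 if stratified else 0.03
        assert np.abs(emp - cdf).max() < tol

    def test_stratified_shrinks_cdf_error(self, rng):
        comps = ((12.0, 2.0, 1.0),)
        grid = np.linspace(0, TWO_PI, 512, endpoint=False)
        pdf = mixture_density(comps, grid)
        cdf = np.cumsum(pdf) * (TWO_PI / grid.size)

        def max_err(stratified, seed):
            t = sample_mixture(comps, 200, np.random.default_rng(seed), stratified=stratified)
            emp = np.searchsorted(np.sort(t), grid, side="right") / t.size
            return np.abs(emp - cdf).max()

        iid = np.mean([max_err(False, s) for s in range(20)])
        strat = np.mean([max_err(True, s) for s in range(20)])
        assert strat < iid / 3


class TestOccupancy:
    def test_marginals_match_targets(self):
        cfg = small_config(n_sites=10, stations_per_site=100)
        pres = simulate_occupancy(cfg)
        assert abs(pres["day"].mean() - 0.5) < 0.03
        assert abs(pres["night"].mean() - 0.4) < 0.03

    def test_independent_species_have_unit_odds_ratio(self):
        cfg = small_config(n_sites=20, stations_per_site=100, seed=3)
        pres = simulate_occupancy(cfg)
        a, b = pres["day"].to_numpy(), pres["night"].to_numpy()
        n11 = ((a == 1) & (b == 1)).sum()
        n00 = ((a == 0) & (b == 0)).sum()
        n10 = ((a == 1) & (b == 0)).sum()
        n01 = ((a == 0) & (b == 1)).sum()
        odds = (n11 * n00) / (n10 * n01)
        assert 0.75 < odds < 1.33

    @pytest.mark.parametrize("target_or", [5.0, 0.2])
    def test_configured_odds_ratio_recovered(self, target_or):
        cfg = small_config(
            n_sites=40, stations_per_site=100, seed=5,
            association=np.array([[1.0, target_or], [target_or, 1.0]]),
        )
        pres = simulate_occupancy(cfg)
        a, b = pres["day"].to_numpy(), pres["night"].to_numpy()
        odds = (((a & b).sum() * ((1 - a) & (1 - b)).sum())
                / ((a & ~b.astype(bool)).sum() * (~a.astype(bool) & b).sum()))
        assert odds == pytest.approx(target_or, rel=0.35)
        # marginals still honoured under association
        assert abs(a.mean() - 0.5) < 0.03

    def test_positive_pair_detected_by_cooccurrence_model(self):
        """An odds-ratio-5 pair at survey-like margins yields a positive
        classification with power > 0.8."""
        hits = 0
        reps = 25
        for seed in range(reps):
            cfg = small_config(
                n_sites=9, stations_per_site=35, seed=100 + seed,
                species=(
                    SpeciesProfile("a", ((12.0, 4.0, 1.0),), 0.2, 0.32),
                    SpeciesProfile("b", ((0.0, 3.0, 1.0),), 0.15, 0.32),
                ),
                association=np.array([[1.0, 5.0], [5.0, 1.0]]),
            )
            pres = simulate_occupancy(cfg)
            a, b = pres["a"].to_numpy() > 0, pres["b"].to_numpy() > 0
            _, p_gt = cooccurrence_test(len(pres), int(a.sum()), int(b.sum()), int((a & b).sum()))
            hits += p_gt < 0.05
        assert hits / reps > 0.8

    def test_negative_association_detectable(self):
        cfg = small_config(
            n_sites=9, stations_per_site=35, seed=7,
            species=(
                SpeciesProfile("a", ((12.0, 4.0, 1.0),), 0.2, 0.45),
                SpeciesProfile("b", ((0.0, 3.0, 1.0),), 0.15, 0.45),
            ),
            association=np.array([[1.0, 0.15], [0.15, 1.0]]),
        )
        pres = simulate_occupancy(cfg)
        a, b = pres["a"].to_numpy() > 0, pres["b"].to_numpy() > 0
        p_lt, _ = cooccurrence_test(len(pres), int(a.sum()), int(b.sum()), int((a & b).sum()))
        assert p_lt < 0.05


class TestDetections:
    def test_zero_rate_produces_no_records(self):
        cfg = small_config(
            species=(SpeciesProfile("quiet", ((12.0, 4.0, 1.0),), 0.0, 0.5),),
            association=np.ones((1, 1)),
        )
        assert simulate_detections(cfg).empty

    def test_diurnal_mixture_confines_detections_to_daylight(self):
        cfg = small_config(
            species=(SpeciesProfile("day", ((12.0, 4.0, 1.0),), 0.5, 0.8),),
            association=np.ones((1, 1)),
        )
        rec = simulate_detections(cfg)
        hours = rec["datetime"].dt.hour + rec["datetime"].dt.minute / 60
        assert ((hours >= 6) & (hours < 18)).mean() > 0.95

    def test_burst_injection_reduces_filtered_fraction(self):
        lo = simulate_detections(small_config(burst_prob=0.0))
        hi = simulate_detections(small_config(burst_prob=0.4))
        ratio_lo = len(filter_independent_events(lo)) / len(lo)
        ratio_hi = len(filter_independent_events(hi)) / len(hi)
        assert ratio_hi < ratio_lo

    def test_schema_matches_ingest_contract(self):
        rec = simulate_detections(small_config())
        assert list(rec.columns) == ["site", "station", "species", "datetime", "count"]
        assert (rec["count"] >= 1).all()
        assert rec["datetime"].dt.second.eq(0).all()  # minute precision

    def test_determinism_identical_seed_identical_csv(self, tmp_path):
        cfg = study_replica_config(seed=42)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_detections(cfg).to_csv(p1, index=False)
        simulate_detections(study_replica_config(seed=42)).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generated_schedules_are_non_uniform(self, rng):
        t = sample_mixture(((7.0, 2.0, 0.5), (17.0, 1.5, 0.5)), 150, rng)
        assert hermans_rasson_test(t, n_boot=500, seed=1).p_value < 0.01


class TestStudyReplica:
    def test_event_totals_track_published_table(self):
        cfg = with_seed(study_replica_config(), 19)
        events = filter_independent_events(simulate_detections(cfg))
        totals = events.groupby("species").size()
        for sp, (target, _, _) in duikerdata.DIEL_COUNTS.items():
            assert totals[sp] == pytest.approx(target, rel=0.10)
        assert totals.sum() == pytest.approx(4358, rel=0.10)

    def test_replica_effort_mirrors_survey_design(self):
        cfg = study_replica_config()
        assert cfg.n_sites == 12
        assert cfg.n_stations * cfg.days_per_station == pytest.approx(17827, rel=0.01)
        assert {p.name for p in cfg.species} == set(duikerdata.SPECIES)
        assert cfg.association.shape == (6, 6)

    def test_group_sizes_mostly_singletons(self):
        rec = simulate_detections(with_seed(study_replica_config(), 23))
        congica = rec[rec["species"] == "P. congica"]["count"]
        leuco = rec[rec["species"] == "C. leucogaster"]["count"]
        assert (leuco == 1).all()  # always photographed alone
        assert 0.08 < (congica >= 2).mean() < 0.20  # lives in pairs
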