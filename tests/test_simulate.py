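"""The synthetic MA-experiment generator: distributions, invariants, round trips."""

import math

import numpy as np
import pytest

from mamut.rates import estimate_rate
from mamut.simulate import (
    SimConfig,
    default_class_rates,
    simulate_genome,
    simulate_ma_experiment,
    write_truth_set,
)
from mamut.spectra import MutationClass, classify_substitution


def test_degenerate_composition_yields_only_at():
    seq = simulate_genome(10_000, 0.0, seed=1)
    assert set(seq) <= {"A", "T"}
    seq = simulate_genome(10_000, 1.0, seed=1)
    assert set(seq) <= {"G", "C"}


def test_realized_gc_within_binomial_bound():
    length, gc = 1_000_000, 0.25
    seq = simulate_genome(length, gc, seed=7)
    realized = (seq.count("G") + seq.count("C")) / length
    assert abs(realized - gc) < 3 * math.sqrt(gc * (1 - gc) / length)


def test_genome_reproducible_for_fixed_seed():
    assert simulate_genome(50_000, 0.3, seed=7) == simulate_genome(50_000, 0.3, seed=7)
    assert simulate_genome(50_000, 0.3, seed=7) != simulate_genome(50_000, 0.3, seed=8)


def test_genome_rejects_bad_arguments():
    with pytest.raises(ValueError):
        simulate_genome(0, 0.25, seed=1)
    with pytest.raises(ValueError):
        simulate_genome(10, 1.5, seed=1)


def test_zero_rates_give_zero_mutations():
    config = SimConfig(
        genome_length=10_000, n_lines=4,
        class_rates={cls: 0.0 for cls in MutationClass}, rng_seed=3,
    )
    truth = simulate_ma_experiment(config)
    assert all(not calls for calls in truth.mutations.values())
    assert truth.manifest["n_mutations"] == 0


def test_experiment_deterministic_and_line_stable():
    """Same seed reproduces the TruthSet; adding lines keeps earlier lines."""
    base = dict(genome_length=50_000, gc_content=0.25,
                class_rates=default_class_rates(1e-6), callable_fraction=0.7,
                rng_seed=11)
    a = simulate_ma_experiment(SimConfig(n_lines=2, **base))
    b = simulate_ma_experiment(SimConfig(n_lines=2, **base))
    assert a.mutations == b.mutations
    assert a.reference == b.reference
    bigger = simulate_ma_experiment(SimConfig(n_lines=4, **base))
    for line_id in a.mutations:
        assert bigger.mutations[line_id] == a.mutations[line_id]
        assert (bigger.masks[line_id] == a.masks[line_id]).all()


@pytest.fixture(scope="module")
def partial_truth():
    return simulate_ma_experiment(
        SimConfig(
            genome_length=80_000, gc_content=0.3, n_lines=5,
            class_rates=default_class_rates(5e-7, gc_content=0.3),
            callable_fraction=0.6, rng_seed=19,
        )
    )


def test_truth_invariants(partial_truth):
    """Calls lie in the mask, match the reference, and never repeat a site."""
    genome = partial_truth.reference["scaffold_1"]
    for line_id, calls in partial_truth.mutations.items():
        mask = partial_truth.masks[line_id]
        positions = [c.position for c in calls]
        assert len(set(positions)) == len(positions)
        for call in calls:
            assert genome[call.position - 1] == call.ref_base
            assert mask[call.position - 1]
            assert call.ref_base != call.alt_base


def test_manifest_counts_match_emitted_calls(partial_truth):
    for line_id, calls in partial_truth.mutations.items():
        realized = partial_truth.manifest["realized_counts"][line_id]
        for cls in MutationClass:
            emitted = sum(
                1 for c in calls
                if classify_substitution(c.ref_base, c.alt_base) is cls
            )
            assert realized[cls.label] == emitted


def test_metadata_counts_callable_site_classes(partial_truth):
    genome = np.frombuffer(
        partial_truth.reference["scaffold_1"].encode(), dtype=np.uint8
    )
    is_at = (genome == ord("A")) | (genome == ord("T"))
    for meta in partial_truth.lines:
        mask = partial_truth.masks[meta.line_id]
        assert meta.callable_sites_AT == int((is_at & mask).sum())
        assert meta.callable_sites_GC == int((~is_at & mask).sum())
        assert abs(mask.sum() - 0.6 * 80_000) <= 1  # exact-size subset


def test_total_count_near_poisson_mean_at_study_scale():
    """5 Mb x 32 lines x 800 divisions at 2.44e-11 gives ~3 mutations:
    the rare-event regime these experiments live in."""
    config = SimConfig(
        genome_length=5_000_000, gc_content=0.25, n_lines=32,
        transfers_per_line=160, divisions_per_cycle=5.0,
        class_rates=default_class_rates(2.44e-11), callable_fraction=1.0,
        rng_seed=100,
    )
    truth = simulate_ma_experiment(config)
    lam = 2.44e-11 * 5e6 * 800 * 32
    total = truth.manifest["n_mutations"]
    assert abs(total - lam) < 3 * math.sqrt(lam)


def test_simulator_calibration_against_poisson_means():
    """Mean per-class counts over 200 replicates sit within 3 SE of theory."""
    n_reps = 200
    rates = default_class_rates(5e-7, gc_content=0.25)
    totals = {cls: 0 for cls in MutationClass}
    site_products = []
    for rep in range(n_reps):
        config = SimConfig(
            genome_length=20_000, gc_content=0.25, n_lines=1,
            transfers_per_line=156, divisions_per_cycle=5.1,
            class_rates=rates, callable_fraction=1.0, rng_seed=10_000 + rep,
        )
        truth = simulate_ma_experiment(config)
        meta = truth.lines[0]
        site_products.append((meta.callable_sites_AT, meta.callable_sites_GC))
        for cls in MutationClass:
            totals[cls] += truth.manifest["total_counts"][cls.label]
    divisions = 156 * 5.1
    for cls in MutationClass:
        mean_sites = np.mean([
            at if cls.source_pair == "AT" else gc for at, gc in site_products
        ])
        lam = rates[cls] * mean_sites * divisions
        se = math.sqrt(lam / n_reps)
        assert abs(totals[cls] / n_reps - lam) < 3 * se, cls


def test_round_trip_through_files(small_truth, written_truth):
    from mamut import io as mio

    out, paths = written_truth
    reference = mio.read_fasta(paths["reference"])
    assert reference == small_truth.reference
    assert mio.read_line_metadata(paths["metadata"]) == small_truth.lines
    for meta in small_truth.lines:
        calls = mio.read_vcf_calls(paths[f"vcf:{meta.line_id}"])
        assert calls == small_truth.mutations[meta.line_id]
        mask = mio.read_bed_mask(
            paths[f"bed:{meta.line_id}"], len(reference["scaffold_1"])
        )
        assert (mask == small_truth.masks[meta.line_id]).all()


def test_write_refuses_overwrite(small_truth, written_truth, tmp_path):
    out, _ = written_truth
    with pytest.raises(FileExistsError):
        write_truth_set(small_truth, out)
    write_truth_set(small_truth, out, overwrite=True)  # explicit flag allowed


def test_vcf_coordinates_are_one_based(tmp_path):
    from mamut.rates import LineMeta
    from mamut.simulate import TruthSet
    from mamut.spectra import MutationCall

    genome = "ACGT" * 10
    mask = np.ones(40, dtype=bool)
    truth = TruthSet(
        reference={"scaffold_1": genome},
        lines=[LineMeta("line_001", 10, 5.0, 20, 20)],
        mutations={"line_001": [MutationCall("line_001", "scaffold_1", 17, "A", "T")]},
        masks={"line_001": mask},
        manifest={"config": {}, "n_mutations": 1},
    )
    paths = write_truth_set(truth, tmp_path / "t")
    vcf_lines = [
        line for line in paths["vcf:line_001"].read_text().splitlines()
        if not line.startswith("#")
    ]
    assert len(vcf_lines) == 1
    fields = vcf_lines[0].split("\t")
    assert (fields[0], fields[1], fields[3], fields[4]) == ("scaffold_1", "17", "A", "T")
    assert "1/1" in fields[9]


def test_empty_truth_set_writes_reference_and_metadata_only(tmp_path):
    from mamut.simulate import TruthSet

    truth = TruthSet(
        reference={"scaffold_1": "ACGTACGT"},
        lines=[], mutations={}, masks={}, manifest={"config": {}, "n_mutations": 0},
    )
    paths = write_truth_set(truth, tmp_path / "empty")
    assert paths["reference"].exists()
    assert paths["metadata"].exists()
    assert not list((tmp_path / "empty").glob("*.vcf"))
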