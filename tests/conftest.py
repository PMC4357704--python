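import pytest

from oritime import synth as sy


@pytest.fixture(scope="session")
def chip_scenario():
    """Genome, timing profile and ChIP/input tracks at the ChIP study scale."""
    cfg = sy.chip_config(seed=7)
    genome = sy.make_genome(cfg, early_fraction=0.5)
    profile = sy.make_timing_profile(genome, cfg)
    mark = sy.make_chip_track(genome, "H3K4me3", cfg)
    inp = sy.make_chip_track(genome, "input", cfg)
    return cfg, genome, profile, mark, inp


@pytest.fixture(scope="session")
def combing_scenario():
    """Control and knockdown fiber sets at the combing study scale."""
    cfg = sy.combing_config(seed=11, n_fibers=900)
    genome = sy.make_genome(cfg, early_fraction=1.0,
                            conditions={"control": 1.0, "knockdown": 0.5})
    control = sy.make_fibers(genome, "control", cfg)
    knockdown = sy.make_fibers(genome, "knockdown", cfg)
    return cfg, genome, control, knockdown


@pytest.fixture()
def single_origin_fibers():
    """One origin firing with the pulse on an unbroken molecule."""
    cfg = sy.SimulationConfig(
        seed=3, chrom_length=10_000_000, origin_spacing_mean=100.0,
        firing_spread_minutes=0.0, label_start_minutes=0.0,
        fiber_length_mean=1e6, measurement_noise_kb=0.0, n_fibers=1,
    )
    origin = sy.Origin(position=5_000_000, timing_class="early", firing_time=0.0)
    genome = sy.GenomeModel(
        chrom_name="chrS", chrom_length=10_000_000, origins=(origin,),
        fork_speed=1.5, conditions={"on": 1.0, "off": 0.0},
    )
    return cfg, genome
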