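import pytest

from zwscan import (CallerThresholds, call_regions, demo_layout, scan_sync,
                    simulate_pool_counts)
from zwscan.simulate import SimLayout, segment

# scan parameters matched to the 1:1000 demo scale (50:1 window:step, as in
# the full-scale 50 kb / 1 kb scan); the female-specific SNP floor scales
# with the window span (background is ~0 SNPs per 1-kb window)
DEMO_WINDOW = 1_000
DEMO_STEP = 100
DEMO_CALLER = CallerThresholds(smoothing_width=11, min_region_span=2 * DEMO_WINDOW,
                               fspec_floor=10)


@pytest.fixture(scope="session")
def demo_sim():
    """Demo ZW chromosome (44 kb, PWR 0-3 kb / CHR 3-20 kb / PAR 20-44 kb)."""
    layout = demo_layout(seed=11)
    records, truth = simulate_pool_counts(layout)
    return layout, records, truth


@pytest.fixture(scope="session")
def demo_windows(demo_sim):
    layout, records, _ = demo_sim
    return scan_sync(iter(records), {layout.chrom_name: layout.total_length},
                     window=DEMO_WINDOW, step=DEMO_STEP)


@pytest.fixture(scope="session")
def demo_calls(demo_windows):
    return call_regions(demo_windows, DEMO_CALLER)


@pytest.fixture(scope="session")
def null_sim():
    """A pure pseudoautosomal chromosome: no divergence, equal multipliers."""
    layout = SimLayout(chrom_name="chrNull", segments=(segment("PAR", 44_000),),
                       baseline_depth=25.0, error_rate=0.002, seed=23)
    records, truth = simulate_pool_counts(layout)
    return layout, records, truth
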