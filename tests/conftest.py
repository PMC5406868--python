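import numpy as np
import pandas as pd
import pytest

import xhyb


@pytest.fixture
def small_layout():
    """Two probe sets x two pairs, fixed ids."""
    return xhyb.ChipLayout(
        pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4"],
                "probe_set_id": ["S1", "S1", "S2", "S2"],
                "pair_index": [0, 1, 0, 1],
            }
        )
    )


@pytest.fixture
def default_sheet():
    """Two genotypes x (3, 4, 3) replicates: the emulated study design."""
    return xhyb.simulate_sample_sheet()


@pytest.fixture
def noise_free_run():
    """Small noise-free dataset with planted DE and full probe binding."""
    layout = xhyb.simulate_layout(120, 5, seed=11)
    truth = xhyb.simulate_truth(
        layout, n_de_per_genotype=20, n_common_de=4, seed=12
    )
    gdna = xhyb.simulate_gdna(layout, 1.0, seed=13, truth=truth)
    sheet = xhyb.simulate_sample_sheet()
    rna = xhyb.simulate_rna(layout, truth, sheet, noise_sd=0.0, seed=14)
    return layout, truth, gdna, sheet, rna


def full_mask(layout, genotype="DipC"):
    gdna_like = pd.Series(1e6, index=layout.probe_ids)
    return xhyb.select_probe_pairs(gdna_like, layout, 0.0, genotype=genotype)


@pytest.fixture
def expr_for(noise_free_run):
    """Factory: noise-free masked expression matrix for one genotype."""
    layout, truth, gdna, sheet, rna = noise_free_run

    def build(genotype, normalize=False):
        active = sheet.active()
        cols = list(active.loc[active["genotype"] == genotype, "sample_id"])
        sub = xhyb.ProbeIntensityMatrix(rna.values[cols])
        mask = full_mask(layout, genotype)
        cfg = xhyb.SummarizationConfig(normalize=normalize)
        return xhyb.rma_summarize(sub, mask, layout, cfg)

    return build
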