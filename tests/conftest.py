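import numpy as np
import pytest

import dysbioformer as d


@pytest.fixture(scope="session")
def small_tree():
    return d.simulate_tree(10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_tree):
    """Two-study cohort with two strongly planted taxa."""
    cfg = d.SimConfig(
        n_taxa=10,
        studies=[("s1", 15, 15), ("s2", 15, 15)],
        effect_taxa={"taxon_0003": 2.0, "taxon_0007": 2.0},
        batch_shift_sd=0.3,
        batch_scale_sd=0.05,
        sequencing_depth_mean=5000,
        seed=11,
    )
    counts, meta, truth = d.simulate_cohorts(cfg, small_tree)
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_tokens(small_tree, small_cohort):
    """Normalized token batch + phylo model for the small cohort."""
    counts, meta, _ = small_cohort
    frac = d.zero_replace(counts)
    clr = d.clr_transform(frac)
    pm = d.kernel_features(d.phylo_kernel(small_tree, counts.taxa), 8)
    raw = d.build_token_sets(clr, frac, counts, pm)
    state = d.fit_normalizer(raw, token_dim=16, seed=5)
    return d.apply_normalizer(raw, state), state, pm


@pytest.fixture()
def tiny_net(small_tokens):
    tokens, state, _ = small_tokens
    cfg = d.ModelConfig(
        token_dim=16, sab_layers=2, n_heads=4, pma_seeds=4,
        ffn_dim=32, head_hidden=16, dropout=0.2, seed=5,
    )
    return d.DysbioNet(tokens.feature_dim, tokens.phylo_dim, cfg, tokenizer_state=state)
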