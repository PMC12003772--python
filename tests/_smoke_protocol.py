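"""Shared desk-scale training-smoke protocol used by the acceptance tests."""
import numpy as np

import grnformer as gf
from grnformer.losses import DownsampleConfig, downsample
from grnformer.synthetic import default_gene_table


def run_training_smoke(seed: int, steps: int = 2000):
    """Train a 2-layer/2-head/d=64 model on 5k synthetic cells and score
    held-out denoising at r=0.7.  Returns (loss_first50, loss_last50, delta)."""
    genes = [f"G{j:05d}" for j in range(25)]
    grn = gf.PlantedGRN.random(genes, edge_prob=0.1, seed=seed)
    cfg = gf.SyntheticConfig(n_cells=5000, n_genes=50, mean_depth=500, seed=seed)
    data = gf.generate_dataset(cfg, grn)
    table = default_gene_table(data.gene_ids, seed=seed)
    vocab = gf.GeneVocabulary.from_gene_table(table, d=64, seed=seed)
    onto = gf.make_ontology(8, 2, seed=seed)
    model = gf.Model(
        gf.ModelConfig(n_layers=2, n_heads=2, d=64, context_size=50),
        vocab, {"cell_type": onto}, seed=seed,
    )
    hold = data.subset_cells(np.arange(100))
    trainset = data.subset_cells(np.arange(100, data.n_cells))
    log = gf.train(model, trainset, gf.TrainConfig.toy(steps=steps, seed=seed),
                   context_size=50)
    first = float(np.mean([e["loss"] for e in log[:50]]))
    last = float(np.mean([e["loss"] for e in log[-50:]]))
    rng = np.random.default_rng(seed)
    noisy = downsample(hold.counts, DownsampleConfig(r=0.7), rng)
    den, _ = gf.denoise(model, noisy, target_depth=hold.totals.astype(float))
    rep = gf.evaluate_denoising(hold.counts, noisy, den)
    return first, last, rep.mean_delta
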