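import numpy as np
import pandas as pd
import pytest

from ribore import footprints as fp
from ribore import readthrough as rt
from ribore import transcriptome as tx
from ribore.synthetic_data import (SyntheticConfig, assign_true_re,
                                   generate_transcriptome, simulate_footprints)


def make_model(utr5="ACGUA", cds="AUGGCUCCAUAA", utr3="GGGUAAACGU", **kw):
    """Hand-built transcript model for unit tests."""
    return tx.TranscriptModel(
        id=kw.get("id", "toy"),
        seq=utr5 + cds + utr3,
        utr5_len=len(utr5),
        cds_len=len(cds),
        utr3_len=len(utr3),
        utr3_annotated=kw.get("utr3_annotated", True),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but deep synthetic library shared across tests.

    60 genes, frame-0 CDS density 4 reads/nt, baseline log2 RE −3 so the
    3'-UTR carries enough reads for stable estimates.
    """
    cfg = SyntheticConfig(n_genes=60, seed=11, cds_read_density=4.0,
                          re_mean=-3.0, re_sd=0.8)
    models, truth = generate_transcriptome(cfg)
    truth = assign_true_re(truth, {}, cfg.re_sd, baseline=cfg.re_mean,
                           seed=cfg.seed + 3)
    raw = simulate_footprints(models, truth, cfg)
    offsets = cfg.offset_table()
    kept, _ = fp.filter_by_length(raw)
    recs, _ = fp.annotate([fp.assign_psite(r, offsets) for r in kept], models)
    regionmaps = {g: tx.locate_extension(m) for g, m in models.items()}
    return {"config": cfg, "models": models, "truth": truth, "raw": raw,
            "records": recs, "regionmaps": regionmaps, "offsets": offsets}


@pytest.fixture(scope="session")
def small_estimates(small_sim):
    counts = fp.count_region_frames(small_sim["records"], small_sim["models"],
                                    small_sim["regionmaps"])
    ests = [
        rt.compute_readthrough_efficiency(
            counts[g], small_sim["models"][g], small_sim["regionmaps"][g])
        for g in sorted(small_sim["models"])
    ]
    ests = rt.apply_expression_filters(ests)
    return rt.classify_high_low(ests)
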