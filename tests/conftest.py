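import numpy as np
import pandas as pd
import pytest

from tfcatalog import ExpressionSet, SimConfig, gen_transcriptome


@pytest.fixture(scope="session")
def clean_sim():
    """A decoy-free synthetic transcriptome with ground truth (session-wide)."""
    cfg = SimConfig(n_genes=50, frac_tf=0.4, decoy_frac=0.0, seed=7)
    transcripts, hits, truth = gen_transcriptome(cfg)
    return cfg, transcripts, hits, truth


def make_expression_set(tpm_by_region: dict[str, list[float]],
                        genes: list[str] | None = None,
                        n_replicates: int = 2,
                        length: float = 1000.0) -> ExpressionSet:
    """Build a regional ExpressionSet whose per-region TPM is exactly as given.

    All genes share one effective length and a filler gene (``zz_filler``)
    tops every column up to 1e6 counts, so each listed gene's TPM equals the
    requested value; each region gets identical replicates.  Callers passing
    per-gene arrays (e.g. ppde tables) must append a filler entry.
    """
    regions = list(tpm_by_region)
    n_genes = len(next(iter(tpm_by_region.values())))
    genes = (genes or [f"g{i}" for i in range(n_genes)]) + ["zz_filler"]
    cols, meta, data = [], [], []
    for r in regions:
        vals = np.asarray(tpm_by_region[r], dtype=float)
        col = np.append(vals, 1e6 - vals.sum())
        for rep in range(1, n_replicates + 1):
            cols.append(f"{r}_{rep}")
            meta.append((f"{r}_{rep}", r, rep))
            data.append(col)
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    metadata = pd.DataFrame(meta, columns=["sample", "region", "replicate"]
                            ).set_index("sample")
    lengths = pd.Series(length, index=genes, name="eff_length")
    return ExpressionSet(counts=counts, eff_length=lengths, metadata=metadata)
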