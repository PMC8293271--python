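import numpy as np
import pandas as pd
import pytest

from hepamark import synthetic as syn
from hepamark import preprocess as pp


@pytest.fixture(scope="session")
def library():
    return syn.packaged_fingerprints()


@pytest.fixture(scope="session")
def tiny_library():
    """Small synthetic fingerprint set with known proton counts, for RC
    ground-truth arithmetic (the packaged proton counts are reference
    values, not ground truth)."""
    peaks = [
        syn.MetabolitePeak("metA", "SYN0001", "singlet", 2.005, 2.005, 3),
        syn.MetabolitePeak("metB", "SYN0002", "singlet", 6.005, 6.005, 1),
        syn.MetabolitePeak("metB", "SYN0002", "doublet", 7.055, 7.065, 3),
        syn.MetabolitePeak("metC", "SYN0003", "singlet", 4.80, 4.80, 2),
    ]
    return syn.FingerprintLibrary(
        peaks=peaks, provenance={p.metabolite: "user" for p in peaks}
    )


@pytest.fixture(scope="session")
def study(library):
    """One simulated study at the default (paper-scale) conditions."""
    seed = 7
    pheno = syn.generate_phenotypes(seed=seed)
    conc = syn.simulate_concentrations(
        pheno, syn.default_effects(), metabolites=library.non_decoys, seed=seed
    )
    spectra = syn.render_study(conc, library, seed=seed)
    normalized = pp.normalize_buckets(pp.bucket_spectra(spectra))
    y_lw = pheno.set_index("sample_id").loc[normalized.values.index, "LW"].to_numpy()
    return {
        "seed": seed,
        "pheno": pheno,
        "conc": conc,
        "spectra": spectra,
        "normalized": normalized,
        "y_lw": y_lw,
    }
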