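"""Published benchmark values bundled with the package.

``REFERENCE_ENRICHMENT`` holds the significantly enriched Reactome
pathways reported for the 120-protein CGSig set of the mouse molar
low-dietary-protein study: found count x, pathway size K, printed
entity ratio (4 decimals) and printed entities p-value.  The table
serves two purposes: recovering the unpublished background proteome
size N from the (K, ratio) pairs, and regression-checking the
hypergeometric enrichment math against an independent implementation's
printed output.

The printed p-values embed the original web service's query-to-entity
identifier mapping, so small third-decimal deviations from the exact
hypergeometric tail are expected and documented rather than absorbed.
"""

from __future__ import annotations

from functools import lru_cache

from .enrichment import BackgroundFit, infer_background

__all__ = [
    "REFERENCE_ENRICHMENT",
    "REFERENCE_QUERY_SIZE",
    "DEFAULT_BACKGROUND",
    "fit_reference_background",
]

#: Query size of the benchmark differential-expression set.
REFERENCE_QUERY_SIZE = 120

#: (pathway_id, name, found x, size K, printed entity ratio, printed p)
REFERENCE_ENRICHMENT: list[tuple[str, str, int, int, float, float]] = [
    ("R-MMU-1266738", "Developmental Biology", 19, 573, 0.0520, 0.0000),
    ("R-MMU-6798695", "Neutrophil degranulation", 14, 532, 0.0483, 0.0020),
    ("R-MMU-6805567", "Keratinization", 13, 191, 0.0173, 0.0000),
    ("R-MMU-397014", "Muscle contraction", 9, 180, 0.0163, 0.0002),
    ("R-MMU-5357801", "Programmed cell death", 5, 151, 0.0137, 0.0253),
    ("R-MMU-381426", "Regulation of IGF transport and uptake by IGFBPs",
     4, 123, 0.0112, 0.0462),
    ("R-MMU-8957275", "Posttranslational protein phosphorylation",
     4, 117, 0.0106, 0.0397),
    ("R-MMU-109581", "Apoptosis", 5, 110, 0.0100, 0.0073),
    ("R-MMU-1169410", "Antiviral mechanism by IFN-stimulated genes",
     4, 101, 0.0092, 0.0251),
    ("R-MMU-6807878", "COPI-mediated anterograde transport", 4, 100, 0.0091, 0.0243),
    ("R-MMU-1500931", "Cell-Cell communication", 4, 100, 0.0091, 0.0243),
    ("R-MMU-6809371", "Formation of the cornified envelope", 13, 98, 0.0089, 0.0000),
    ("R-MMU-373760", "L1CAM interactions", 4, 76, 0.0069, 0.0099),
    ("R-MMU-446728", "Cell junction organization", 4, 76, 0.0069, 0.0099),
    ("R-MMU-9013106", "RHOC GTPase cycle", 3, 75, 0.0068, 0.0493),
    ("R-MMU-9013026", "RHOB GTPase cycle", 3, 74, 0.0067, 0.0477),
    ("R-MMU-9833482", "PKR-mediated signaling", 4, 71, 0.0064, 0.0078),
    ("R-MMU-3371497", "HSP90 chaperone cycle for SHR in the presence of ligand",
     3, 71, 0.0064, 0.0431),
    ("R-MMU-75105", "Fatty acyl-CoA biosynthesis", 3, 70, 0.0064, 0.0417),
    ("R-MMU-9013406", "RHOQ GTPase cycle", 3, 62, 0.0056, 0.0308),
    ("R-MMU-3000178", "ECM proteoglycans", 4, 52, 0.0047, 0.0026),
    ("R-MMU-75153", "Apoptotic execution phase", 4, 50, 0.0045, 0.0023),
    ("R-MMU-375165", "NCAM signaling for neurite out-growth", 3, 45, 0.0041, 0.0134),
    ("R-MMU-390522", "Striated muscle contraction", 6, 39, 0.0035, 0.0000),
    ("R-MMU-111465", "Apoptotic cleavage of cellular proteins", 4, 38, 0.0034, 0.0008),
    ("R-MMU-1237044", "Erythrocytes take up carbon dioxide and release oxygen",
     3, 24, 0.0022, 0.0024),
    ("R-MMU-1480926", "O2/CO2 exchange in erythrocytes", 3, 24, 0.0022, 0.0024),
    ("R-MMU-140875", "Common pathway of fibrin clot formation", 2, 24, 0.0022, 0.0286),
    ("R-MMU-1475029", "Reversible hydration of carbon dioxide", 2, 17, 0.0015, 0.0151),
    ("R-MMU-1247673", "Erythrocytes take up oxygen and release carbon dioxide",
     3, 16, 0.0015, 0.0008),
    ("R-MMU-445095", "Interaction between L1 and ankyrins", 2, 12, 0.0011, 0.0078),
    ("R-MMU-351906", "Apoptotic cleavage of cell adhesion proteins",
     3, 11, 0.0010, 0.0003),
    ("R-MMU-446107", "Type I hemidesmosome assembly", 2, 9, 0.0008, 0.0045),
    ("R-MMU-5660668", "CLEC7A/inflammasome pathway", 1, 4, 0.0004, 0.0426),
]


@lru_cache(maxsize=1)
def fit_reference_background() -> BackgroundFit:
    """Least-squares fit of the background proteome size N to the
    printed (pathway size, entity ratio) pairs."""
    pairs = [(K, ratio) for _, _, _, K, ratio, _ in REFERENCE_ENRICHMENT]
    return infer_background(pairs)


#: Background proteome size recovered from the printed entity ratios;
#: every one of the 34 printed ratios equals round(K / 11017, 4).
DEFAULT_BACKGROUND = 11017
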