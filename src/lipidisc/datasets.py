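"""Bundled reference tables.

``candidate_species`` returns the published list of 42 candidate bioactive
lipid species — the intersection of the discriminant sets from the
suspension-differentiation time course and the ELOVL1 / SLC27A1 knockdown
time courses — together with the reported maximum mol% fold change of each
species in the knockdown experiment ("Accumulated" marks species that were
undetectable in the control cells, so no ratio could be formed).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nomenclature import LipidSpecies, parse_species_annotation


def candidate_species() -> pd.DataFrame:
    """The 42 published candidate bioactive species.

    Returns a DataFrame with columns ``knockdown`` (siELOVL1/siSLC27A1),
    ``annotation`` (verbatim), ``max_fold_change`` (verbatim string) and
    ``species`` (parsed :class:`~lipidisc.nomenclature.LipidSpecies`).
    """
    ref = resources.files("lipidisc").joinpath("data/candidate_species.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["species"] = [parse_species_annotation(a) for a in df["annotation"]]
    return df


def candidate_species_list() -> list[LipidSpecies]:
    """Just the parsed species of :func:`candidate_species`."""
    return list(candidate_species()["species"])
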