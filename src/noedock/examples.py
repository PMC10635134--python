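"""Packaged example restraint tables for the ARNT PAS-B cavity ligands.

These are synthetic reconstructions, not experimental data: peak tables for
the KG-655 and KG-279 ligands built to reproduce the documented restraint
bookkeeping — 12 interproton restraints expanding to 19 heavy-atom distances
(KG-655, whose degenerate aromatic pair appears in 7 peaks) and 28 expanding
to 31 (KG-279), with cavity/surface/outlier site labels that yield 7 and 6
active residues respectively.
"""

from __future__ import annotations

from importlib import resources

from .restraints import NoePeak, ProtonGroup, read_peak_table, read_proton_groups, read_site_labels


def _data_path(name: str):
    return resources.files("noedock").joinpath("data", name)


def example_proton_groups() -> dict[str, ProtonGroup]:
    with resources.as_file(_data_path("arnt_proton_groups_synthetic.tsv")) as p:
        return read_proton_groups(p)


def example_site_labels() -> dict[int, str]:
    with resources.as_file(_data_path("arnt_site_labels_synthetic.tsv")) as p:
        return read_site_labels(p)


def kg655_peaks() -> list[NoePeak]:
    with resources.as_file(_data_path("kg655_noe_peaks_synthetic.tsv")) as p:
        return read_peak_table(p)


def kg279_peaks() -> list[NoePeak]:
    with resources.as_file(_data_path("kg279_noe_peaks_synthetic.tsv")) as p:
        return read_peak_table(p)
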