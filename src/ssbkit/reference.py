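"""Published reference values for the SSB panel: seven psychrophilic SSBs
(DpsSSB, FpsSSB, ParSSB, PcrSSB, PinSSB, PprSSB, PtoSSB) characterized
alongside the mesophilic EcoSSB, with thermophilic TteSSB3 and TmaSSB as
compositional comparators.

These printed values are inputs: chain lengths and tabulated
physicochemical indices drive the desk-scale reproductions, and the
instrument-level results (native masses, melting temperatures, site sizes,
quenches) parameterize the synthetic scenario bank in :mod:`ssbkit.synth`.
"""

from __future__ import annotations

#: The seven cold-adapted SSBs of the panel, in tabulated order.
PSYCHROPHILIC = ("DpsSSB", "FpsSSB", "ParSSB", "PcrSSB", "PinSSB", "PtoSSB", "PprSSB")

#: Chain lengths (residues, incl. initiator Met) of the characterized panel.
CHAIN_LENGTH = {
    "DpsSSB": 142, "FpsSSB": 140, "ParSSB": 213, "PcrSSB": 219,
    "PinSSB": 222, "PtoSSB": 151, "PprSSB": 183, "EcoSSB": 178,
}

#: Tabulated monomer masses (kDa, 1 dp).
MONOMER_MASS_KDA = {
    "DpsSSB": 15.6, "FpsSSB": 15.9, "ParSSB": 22.8, "PcrSSB": 23.3,
    "PinSSB": 25.1, "PtoSSB": 17.1, "PprSSB": 20.4, "EcoSSB": 18.9,
}

#: Tabulated isoelectric points.
PI = {
    "DpsSSB": 5.46, "FpsSSB": 5.94, "ParSSB": 5.91, "PcrSSB": 5.70,
    "PinSSB": 7.79, "PtoSSB": 5.67, "PprSSB": 5.43, "EcoSSB": 5.44,
}

#: Tabulated aliphatic indices.
ALIPHATIC_INDEX = {
    "DpsSSB": 61.20, "FpsSSB": 73.07, "ParSSB": 49.11, "PcrSSB": 43.29,
    "PinSSB": 41.80, "PtoSSB": 61.32, "PprSSB": 54.37, "EcoSSB": 56.97,
}

#: Tabulated cysteine counts.
CYS_COUNT = {
    "DpsSSB": 1, "FpsSSB": 2, "ParSSB": 0, "PcrSSB": 0,
    "PinSSB": 1, "PtoSSB": 3, "PprSSB": 0, "EcoSSB": 0,
}

#: Native masses (kDa) from analytical gel filtration of the panel.
NATIVE_MASS_KDA = {
    "DpsSSB": 59.0, "FpsSSB": 69.5, "ParSSB": 94.4, "PcrSSB": 96.1,
    "PinSSB": 102.8, "PprSSB": 85.4, "PtoSSB": 72.3,
}

#: Melting temperature (deg C) of the 44-bp reporter duplex alone
#: (0.1 M NaCl) and in the presence of each SSB.
DUPLEX_TM_FREE = 75.0
DUPLEX_TM_WITH_SSB = {
    "DpsSSB": 70.0, "FpsSSB": 69.0, "PinSSB": 69.0, "ParSSB": 67.0,
    "PprSSB": 65.0, "PcrSSB": 64.0, "PtoSSB": 58.0, "EcoSSB": 62.0,
}

#: ssDNA binding-site sizes (nt per tetramer) and saturation quenches from
#: inverse (dT)76 titrations. FpsSSB shows a salt-dependent binding-mode
#: transition; all others are salt independent.
SITE_SIZE_NT = {
    "DpsSSB": 31, "ParSSB": 32, "PcrSSB": 32, "PinSSB": 30,
    "PprSSB": 32, "PtoSSB": 32,
}
FPS_SITE_SIZE_NT = {"low_salt": 31, "high_salt": 45}
QUENCH = {
    "DpsSSB": 0.93, "FpsSSB": 0.93, "ParSSB": 0.93, "PcrSSB": 0.93,
    "PtoSSB": 0.93, "PprSSB": 0.90, "PinSSB": 0.81,
}

#: Titration geometry: protein amount (nmol of tetramer) and titrant length.
TITRATION_PROTEIN_NMOL = 1.5
TITRATION_OLIGO_NT = 76
TITRATION_SALT_MM = (2.0, 100.0, 300.0)

#: Protein melting temperatures (deg C) from calorimetry.
DSC_TM = {
    "ParSSB": 59.9, "PcrSSB": 63.0, "PinSSB": 57.9, "PprSSB": 59.5,
    "PtoSSB": 58.7, "DpsSSB": 78.5, "FpsSSB": 69.4, "EcoSSB": 69.0,
}

#: Gel-filtration calibration standards: (mass kDa, protein).
CALIBRATION_STANDARDS_KDA = (
    (200.0, "beta-amylase"),
    (150.0, "alcohol dehydrogenase"),
    (66.0, "bovine albumin"),
    (29.0, "carbonic anhydrase"),
)

#: Public sequence-database accessions of the panel chains. The sequences
#: themselves are not redistributed with the package; supply them as a
#: local FASTA (ids matching the panel names or these accessions) to
#: :func:`load_panel_sequences`.
ACCESSIONS = {
    "DpsSSB": "WP_011189820.1",
    "FpsSSB": "WP_011963776.1",
    "ParSSB": "AAZ19531.1",
    "PcrSSB": "ABE75735.1",
    "PinSSB": "WP_011771629.1",
    "PprSSB": "WP_011219846.1",
    "PtoSSB": "WP_015023871.1",
    "EcoSSB": "YP_492202.1",
}


def load_panel_sequences(fasta_path=None):
    """Load the panel's chain sequences from a user-supplied FASTA.

    Returns a mapping panel-name -> :class:`~ssbkit.io.SequenceRecord`.
    Records are matched by panel name or by accession (version suffix
    ignored). Raises :class:`FileNotFoundError` when no FASTA is given:
    the chains are public database records (see :data:`ACCESSIONS`) but are
    not bundled, so sequence-level analyses require a local copy.
    """
    if fasta_path is None:
        raise FileNotFoundError(
            "no local FASTA of the panel sequences provided; fetch the public "
            "records listed in ssbkit.reference.ACCESSIONS (e.g. EcoSSB "
            "YP_492202.1) and pass the file path"
        )
    from .io import read_fasta  # local import to avoid a cycle

    by_accession = {v.split(".")[0]: k for k, v in ACCESSIONS.items()}
    panel = {}
    for record in read_fasta(fasta_path):
        base = record.id.split(".")[0]
        if record.id in ACCESSIONS:
            panel[record.id] = record
        elif base in by_accession:
            panel[by_accession[base]] = record
    if not panel:
        raise ValueError(f"no panel sequences recognized in {fasta_path}")
    return panel
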