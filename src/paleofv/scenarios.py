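"""Built-in scenario presets.

``two_event_scenario`` is the package's reference scenario: six
EVE-positive cynipoid species (three *Leptopilina*, *Trybliographa*,
*Trichoplasta*, *Rhoptromeris*) plus three negative relatives, carrying

* an ancestral event of 18 viral gene families (12 of them core genes)
  from an LhFV-like donor in the common ancestor of the six species, and
* a recent event of 9 families from an LbFV-like donor on the
  *Rhoptromeris* branch, realized as 16 loci of which 7 are
  pseudogenized,

with the two gene sets overlapping in 5 families, plus 3 orphan loci
whose families occur in neither event.  Two event families are emitted
with unresolvable (low-support) trees, so exactly 12 families show the
ancestral-only pattern, 3 the recent-only pattern, 5 both, and 5 are
unclassifiable; the orphans stay unassigned while every other locus is
recoverable through colocation and shared-clade homology: 153 loci in
total, 150 assignable to the two events.

The chronogram ages are the published calibration for this wasp group:
crown of the six positive species 76.4 Myr (CI 55-100), the
*Rhoptromeris*-*Trichoplasta* split 40 Myr (CI 22-59), the *Ganaspis*
split 91.1 Myr, and a 145-Myr root.
"""

from __future__ import annotations

from .simulate import (
    EventSpec,
    GenomeParams,
    OmegaParams,
    ScenarioConfig,
    Virus,
    VirusPanel,
)

L_HET = "Leptopilina_heterotoma"
L_BOU = "Leptopilina_boulardi"
L_CLA = "Leptopilina_clavipes"
TRYB = "Trybliographa_sp"
TRICHO = "Trichoplasta_sp"
RHOPT = "Rhoptromeris_sp"
LEPTOLAMINA = "Leptolamina_sp"
GANASPIS = "Ganaspis_sp"
SYNERGUS = "Synergus_sp"

POSITIVE_SPECIES = (L_HET, L_BOU, L_CLA, TRYB, TRICHO, RHOPT)
ALL_SPECIES = POSITIVE_SPECIES + (LEPTOLAMINA, GANASPIS, SYNERGUS)

#: calibrated species chronogram; branch lengths in Myr, credibility
#: intervals as node comments
CHRONOGRAM_NEWICK = (
    f"({SYNERGUS}:145,({GANASPIS}:91.1,({LEPTOLAMINA}:83,"
    f"((({L_HET}:30,({L_BOU}:20,{L_CLA}:20)[&age=20]:10)[&age=30]:30,"
    f"{TRYB}:60)[&age=60]:16.4,"
    f"({TRICHO}:40,{RHOPT}:40)[&age=40,ci={{22,59}}]:36.4)"
    f"[&age=76.4,ci={{55,100}}]:6.6)[&age=83]:8.1)[&age=91.1]:53.9)[&age=145];"
)

# ancestral-event families; the first twelve are Naldaviricetes core genes
EVENT_I_FAMILIES = (
    "dnapol", "helicase", "lef-4", "lef-5", "lef-8", "lef-9",
    "p74", "pif-1", "pif-2", "ac81", "pif-3", "odv-e56",
    "orf108", "orf58", "orf44", "orf85", "orf10", "orf11",
)
CORE_FAMILIES = EVENT_I_FAMILIES[:12]

#: families acquired in both events (the ones showing both tree patterns)
SHARED_FAMILIES = ("orf10", "orf11", "pif-3", "odv-e56", "orf85")

EVENT_II_FAMILIES = SHARED_FAMILIES + ("integrase", "odv-e66", "orf105", "orf92")

ORPHAN_FAMILIES = ("orf7", "orf72", "orf83")

#: event families whose trees are emitted with low support, recoverable
#: only through scaffold colocation
UNCLASSIFIED_EVENT_FAMILIES = ("orf44", "orf105")


def _default_panel() -> VirusPanel:
    filler = tuple(f"LhFV_g{i:02d}" for i in range(1, 93))      # 18 + 92 = 110 genes
    lhfv_core = CORE_FAMILIES + filler[:17]                      # 12 + 17 = 29 core
    lbfv_filler = tuple(f"LbFV_g{i:02d}" for i in range(1, 92))  # 9 + 91 = 100 genes
    pcfv_genes = ORPHAN_FAMILIES + tuple(f"PcFV_g{i:02d}" for i in range(1, 61))
    return VirusPanel(viruses=(
        Virus("LhFV", "LhFV-like", EVENT_I_FAMILIES + filler, lhfv_core),
        Virus("CcFV1", "LhFV-like", EVENT_I_FAMILIES[:10]),
        Virus("CcFV2", "LhFV-like", EVENT_I_FAMILIES[:10]),
        Virus("LbFV", "LbFV-like", EVENT_II_FAMILIES + lbfv_filler,
              ("pif-3", "odv-e56") + lbfv_filler[:20]),
        Virus("EfFV", "LbFV-like", EVENT_II_FAMILIES[:5]),
        Virus("PcFV", "FV-basal", pcfv_genes),
        Virus("GpSGHV", "outgroup", ("dnapol", "helicase", "p74")),
        Virus("MdSGHV", "outgroup", ("dnapol", "helicase", "p74")),
    ))


def _extras(species: str, k: int) -> tuple[tuple[str, str, int], ...]:
    """One extra paralog copy for the first k ancestral-event families."""
    return tuple((species, fam, 1) for fam in EVENT_I_FAMILIES[:k])


def two_event_scenario(seed: int = 4217) -> ScenarioConfig:
    """The reference two-event scenario (153 loci, 6 positive species)."""
    event_i = EventSpec(
        event_id="ancestral",
        donor_lineage="LhFV-like",
        recipient_species=POSITIVE_SPECIES,
        gene_families=EVENT_I_FAMILIES,
        losses=(
            (TRICHO, ("orf10", "orf11")),
            (RHOPT, ("orf10", "orf11", "pif-3", "odv-e56", "orf85")),
        ),
        # 33 extra paralog copies: 101 single-copy presences -> 134 loci
        paralog_extra=(
            _extras(L_HET, 8) + _extras(L_BOU, 14) + _extras(L_CLA, 5)
            + _extras(TRYB, 4) + _extras(TRICHO, 2)
        ),
    )
    event_ii = EventSpec(
        event_id="recent",
        donor_lineage="LbFV-like",
        recipient_species=(RHOPT,),
        gene_families=EVENT_II_FAMILIES,
        # 9 families -> 16 loci through paralog copies
        paralog_extra=(
            (RHOPT, "orf10", 1), (RHOPT, "orf11", 1), (RHOPT, "odv-e56", 1),
            (RHOPT, "odv-e66", 2), (RHOPT, "orf105", 1), (RHOPT, "orf92", 1),
        ),
        # 7 of the 16 copies carry premature stop codons
        pseudogenized=(
            (RHOPT, "orf10", 2), (RHOPT, "orf11", 2), (RHOPT, "odv-e66", 2),
            (RHOPT, "orf92", 2), (RHOPT, "orf105", 1), (RHOPT, "orf105", 2),
            (RHOPT, "integrase", 1),
        ),
        # a single-species event needs its scaffolds chained explicitly:
        # consecutive scaffolds share a (classified) family through split
        # paralog copies, so colocation + same-clade homology connect all 16
        colocation_groups=(
            (RHOPT, (
                ("orf10", "orf11", "pif-3", "orf105", "orf105"),
                ("orf10", "orf11", "integrase", "odv-e66"),
                ("odv-e66", "odv-e66", "odv-e56"),
                ("odv-e56", "orf85", "orf92", "orf92"),
            )),
        ),
    )
    return ScenarioConfig(
        seed=seed,
        chronogram_newick=CHRONOGRAM_NEWICK,
        wasp_species=ALL_SPECIES,
        virus_panel=_default_panel(),
        events=(event_i, event_ii),
        orphan_loci=((L_HET, "orf7"), (TRYB, "orf72"), (TRICHO, "orf83")),
        orphan_neighbor_virus="PcFV",
        unclassified_families=UNCLASSIFIED_EVENT_FAMILIES,
        # lef-5 keeps the donor's alternative TTG start in most genomes;
        # two species reverted to ATG and one shifted to CTG
        alt_start_codons=(
            (L_BOU, "lef-5", "TTG"), (TRYB, "lef-5", "TTG"),
            (RHOPT, "lef-5", "TTG"), (L_CLA, "lef-5", "CTG"),
        ),
        omega=OmegaParams(
            default_omega=0.15,
            # the recent-event odv-e66 copies evolve neutrally; lef-5 and
            # orf10 are strongly conserved
            family_omega=(("odv-e66", 1.0), ("lef-5", 0.11), ("orf10", 0.17)),
        ),
    )


def single_event_scenario(seed: int = 4217) -> ScenarioConfig:
    """Only the ancestral event, no orphans; one recoverable event."""
    base = two_event_scenario(seed)
    return ScenarioConfig(
        seed=seed,
        chronogram_newick=base.chronogram_newick,
        wasp_species=base.wasp_species,
        virus_panel=base.virus_panel,
        events=(base.events[0],),
        orphan_loci=(),
        orphan_neighbor_virus="PcFV",
        unclassified_families=("orf44",),
        omega=base.omega,
    )


def empty_scenario(seed: int = 4217) -> ScenarioConfig:
    """No endogenization at all: negative-control genomes only."""
    base = two_event_scenario(seed)
    return ScenarioConfig(
        seed=seed,
        chronogram_newick=base.chronogram_newick,
        wasp_species=base.wasp_species,
        virus_panel=base.virus_panel,
        events=(),
        orphan_loci=(),
        orphan_neighbor_virus="PcFV",
        genome=GenomeParams(n_decoy_hits_per_negative=0),
    )


PRESETS = {
    "two-event": two_event_scenario,
    "single-event": single_event_scenario,
    "empty": empty_scenario,
}
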