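# Serotonin / HPA-axis / BDNF interaction network, 41 nodes, synchronous
# Boolean semantics.  One rule per line: "TARGET, <expression>" with
# operators & (and), | (or), ! (not).  A node whose rule is its own name is
# an environmental input: it is clamped at its initial value for a whole
# simulation because no other node regulates it.
#
# Inhibitory regulation is written AND-NOT (target active requires the
# activator present and the inhibitor absent); where several activators act
# with no printed operator they combine by OR.  Edges marked "reconstructed"
# are modeling choices where the pathway narrative does not pin down an
# exact Boolean rule; the mechanism is stated in each comment.
#
# Cell compartments: DRN = dorsal raphe nucleus (serotonergic soma);
# SSC = serotonin-sensitive hippocampal cell (postsynaptic); PVN =
# paraventricular nucleus; PG = pituitary gland.  Nodes suffixed _PRE sit on
# the presynaptic (DRN) side, _POST on the postsynaptic side.
targets, factors

# --- environmental inputs (clamped) ---------------------------------------
stress, stress                    # stressor; held at its initial value
TRP, TRP                          # tryptophan availability; held constant
SSRI, SSRI                        # selective serotonin reuptake inhibitor

# --- 5-HT synthesis and degradation (DRN) ----------------------------------
# TPH2 transcription is sustained by BDNF/TRkB signalling, shut off by the
# DRN glucocorticoid receptor, and blocked during autoreceptor-driven
# hyperpolarization (K_PRE).  reconstructed: operator grouping of the three
# regulators is not printed; they combine as AND / AND-NOT.
TPH2, TRKB & !GRMR_DRN & !K_PRE
HTP5, TRP & TPH2                  # 5-HTP: tryptophan hydroxylation product
AADC, TRKB                        # reconstructed: synthesis enzymes are part
                                  # of the TRkB-maintained serotonergic phenotype
HT5_DRN, HTP5 & AADC              # somatic serotonin (5-HT*)
MAOA, TRKB                        # reconstructed: phenotype gene, as AADC
HIAA5, HT5_DRN & MAOA             # 5-HIAA, degradation product (sink node)

# --- vesicular packaging and release ---------------------------------------
SLC18A2, TRKB                     # vesicular monoamine transporter, phenotype gene
VESICLE, HT5_DRN & SLC18A2        # vesicular 5-HT pool
SNARE, VESICLE                    # release of the vesicular pool
# synaptic 5-HT: released 5-HT persists in the cleft until the transporter
# recaptures it.  reconstructed: the persistence term (| HT5_SYN).
HT5_SYN, (SNARE | HT5_SYN) & !HTT

# --- reuptake and autoreceptor branch (DRN) ---------------------------------
# 5-HTT transcription is TRkB-maintained; SSRI blocks the transporter;
# hyperpolarization reduces transport (reconstructed: modeled at 5-HTT).
HTT, TRKB & !SSRI & !K_PRE
# presynaptic autoreceptor 5-HT1A*: activated by synaptic 5-HT, its
# synthesis blocked by TRkB signalling, and blocked by SSRI.
HT1A_PRE, HT5_SYN & !TRKB & !SSRI
KCH_PRE, HT1A_PRE                 # Gi-gated K channel (K-Channel*)
K_PRE, KCH_PRE                    # K+ efflux -> DRN hyperpolarization (K+*)

# --- postsynaptic serotonin-sensitive cell ----------------------------------
HT1A_POST, HT5_SYN & NFKB         # 5-HT1A transcription requires NF-kB
KCH_POST, HT1A_POST               # Gi-gated K channel
K_POST, KCH_POST                  # hippocampal hyperpolarization
NFKB, !GRMR_SSC                   # NF-kB blocked by the SSC glucocorticoid receptor

# --- BDNF / TRkB neurotrophin loop (DRN) ------------------------------------
# Autoreceptor-driven hyperpolarization blocks the BDNF regulatory genes;
# CREB-driven BDNF re-activates TRkB.  TRkB's enhancement of CREB/BDNF is
# carried by relief of this blockade (double-negative form; the cAMP/PKA
# kinase cascade appears as the ubiquitous AC/CAMP/PKA chain below).
# reconstructed: blockade entry point placed at CREB.
CREB, !K_PRE
BDNF, CREB
TRKB, BDNF

# --- HPA stress axis ---------------------------------------------------------
CRH, stress & !GRMR_PVN           # hypothalamic CRH, PVN receptor feedback
VPA, stress & !GRMR_PVN           # vasopressin, same feedback
ACTH, CRH & VPA & !GRMR_PG        # pituitary ACTH, PG receptor feedback
CORT, ACTH                        # adrenal cortisol
GRMR_PG, CORT                     # glucocorticoid/mineralocorticoid receptors
GRMR_PVN, CORT
GRMR_DRN, CORT
GRMR_SSC, CORT

# --- ubiquitously expressed signalling intermediates -------------------------
# Carried as single-input taps off the chains they serve, with no outgoing
# functional edges, so that deleting any of them leaves the 32 displayed
# nodes unchanged.  Not shown in result plots.
GI_PRE, HT1A_PRE                  # presynaptic Gi
GBG_PRE, GI_PRE                   # G-beta/gamma
AC, TRKB                          # adenylyl cyclase (DRN)
CAMP, AC                          # cAMP
PKA, CAMP                         # protein kinase A
GI_POST, HT1A_POST                # postsynaptic Gi
GBG_POST, GI_POST
AC_POST, GI_POST
CAMP_POST, AC_POST
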