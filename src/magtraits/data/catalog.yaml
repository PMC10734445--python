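# Default trait catalog: KEGG/PFAM gene sets for Fe, P, N, vitamin and
# interaction traits of a diazotroph-epibiont consortium.
#
# Conventions
#   - module_genes: ordered KEGG orthologs making up the pathway/system.
#   - marker_genes: subset individually required for a "present" call
#     (substrate-specific receptors / diagnostic subunits).
#   - completeness_threshold: fraction of distinct module genes required
#     (inclusive); default 0.5.
#   - rule marker_companion: marker subunit must co-occur with >=1 companion
#     transporter gene (vitamin-uptake systems).
#   - report_partial: below-threshold evidence is reported as putative.
#
# narGHI is pinned to the dissimilatory subunits {K00370, K00371, K00374};
# K00372 is carried separately as nasA (assimilatory nitrate reductase).
# The cobalamin biosynthesis set transcribes the standard cobinamide->
# cobalamin module orthologs.

traits:
  # ------------------------------------------------------------- iron
  - trait_id: fe2_uptake              # feoB, ferrous iron transport
    category: iron
    module_genes: [K04759]
    marker_genes: [K04759]
  - trait_id: fe3_uptake              # afuA, ferric iron ABC transporter
    category: iron
    module_genes: [K02012]
    marker_genes: [K02012]
  - trait_id: heme_uptake             # hemR, outer-membrane heme receptor
    category: iron
    module_genes: [K16087]
    marker_genes: [K16087]
  - trait_id: citrate_uptake          # fecA, ferric-citrate receptor
    category: iron
    module_genes: [K16091]
    marker_genes: [K16091]
  - trait_id: siderophore_uptake      # fevS; KO does not separate siderophore vs B12 substrate
    category: iron
    module_genes: [K02016]
    marker_genes: [K02016]
  - trait_id: tonb_system             # tonB / exbB / exbD energizing complex
    category: iron
    module_genes: [K03832, K03561, K03559]
    marker_genes: [K03832, K03561, K03559]

  # ------------------------------------------------------- phosphorus
  - trait_id: pst_transporter         # pstSCAB high-affinity phosphate
    category: phosphorus
    module_genes: [K02036, K02037, K02038, K02040]
  - trait_id: pit_transporter         # pitA low-affinity phosphate
    category: phosphorus
    module_genes: [K03306]
    marker_genes: [K03306]
  - trait_id: phn_transporter         # phnCDE / ptxABC (substrate-ambiguous)
    category: phosphorus
    module_genes: [K02041, K02042, K02044]
  - trait_id: ptxD                    # phosphite dehydrogenase
    category: phosphorus
    module_genes: [K18916]
    marker_genes: [K18916]
  - trait_id: cp_lyase                # phnGHIJKLM broad-specificity C-P lyase
    category: phosphorus
    module_genes: [K06162, K06163, K06164, K06165, K06166, K05780, K05781]
  - trait_id: aep_hydrolysis          # phnA/phnX/phnW 2-AEP routes; phnW diagnostic
    category: phosphorus
    module_genes: [K19670, K05306, K03430]
    marker_genes: [K03430]
    report_partial: true
  - trait_id: phoA                    # alkaline phosphatase A
    category: phosphorus
    module_genes: [K01077]
    marker_genes: [K01077]
  - trait_id: phoX
    category: phosphorus
    module_genes: [K07093]
    marker_genes: [K07093]
  - trait_id: phoD
    category: phosphorus
    module_genes: [K01113]
    marker_genes: [K01113]

  # --------------------------------------------------------- nitrogen
  - trait_id: nif                     # nifHKD(+anfG) N2-fixation module; full set required
    category: nitrogen
    module_genes: [K02588, K02591, K02586, K00531]
    marker_genes: [K02588, K02591, K02586, K00531]
  - trait_id: napAB                   # periplasmic nitrate reductase
    category: nitrogen
    module_genes: [K02567, K02568]
  - trait_id: narGHI                  # membrane-bound nitrate reductase
    category: nitrogen
    module_genes: [K00370, K00371, K00374]
  - trait_id: narB                    # assimilatory nitrate reductase (cyanobacterial)
    category: nitrogen
    module_genes: [K00367]
    marker_genes: [K00367]
  - trait_id: nasA                    # assimilatory nitrate reductase, ANRA marker
    category: nitrogen
    module_genes: [K00372]
    marker_genes: [K00372]
  - trait_id: nrfAH                   # cytochrome-c nitrite reductase; nrfA diagnostic for DNRA
    category: nitrogen
    module_genes: [K15876, K03385]
    marker_genes: [K03385]
  - trait_id: nirA                    # assimilatory (ferredoxin) nitrite reductase
    category: nitrogen
    module_genes: [K00366]
    marker_genes: [K00366]
  - trait_id: nirBD                   # NADH nitrite reductase
    category: nitrogen
    module_genes: [K00362, K00363]
  - trait_id: nirS                    # cytochrome cd1 nitrite reductase, denitrification marker
    category: nitrogen
    module_genes: [K15864]
    marker_genes: [K15864]
  - trait_id: nirK                    # copper nitrite reductase, denitrification marker
    category: nitrogen
    module_genes: [K00368]
    marker_genes: [K00368]
  - trait_id: norBC                   # nitric-oxide reductase
    category: nitrogen
    module_genes: [K04561, K02305]
  - trait_id: nosZ                    # nitrous-oxide reductase, terminal denitrification step
    category: nitrogen
    module_genes: [K00376]
    marker_genes: [K00376]

  # ---------------------------------------------------------- vitamin
  - trait_id: vitB1_biosynthesis      # thiCDEGL thiamin biosynthesis
    category: vitamin
    module_genes: [K00946, K00788, K03149, K00941, K03147]
  - trait_id: vitB1_uptake            # thiB binding subunit + thiPQ transporter
    category: vitamin
    module_genes: [K02064, K02063, K02062]
    marker_genes: [K02064]
    rule: marker_companion
  - trait_id: vitB7_biosynthesis      # bioABDF biotin biosynthesis
    category: vitamin
    module_genes: [K01012, K01935, K00833, K00652]
  - trait_id: vitB7_uptake            # bioY binding subunit + bioNM or efcTA1A2
    category: vitamin
    module_genes: [K03523, K16783, K16784, K16785, K16786, K16787]
    marker_genes: [K03523]
    rule: marker_companion
  - trait_id: vitB12_biosynthesis     # cobinamide -> cobalamin module orthologs
    category: vitamin
    module_genes: [K00798, K19221, K02232, K00768, K02225, K02227, K02231, K19712]
  - trait_id: vitB12_uptake           # btuB TBDT receptor + btuF/btuCD ABC system
    category: vitamin
    module_genes: [K16092, K06858, K25034, K06074, K06073]
    marker_genes: [K16092]
    rule: marker_companion

  # ------------------------------------------------------ interaction
  - trait_id: ahl_biosynthesis        # luxR-homolog autoinducer synthesis domain
    category: interaction
    pfam_markers: [PF00765]
  - trait_id: quorum_sensing_regulation   # luxR / bjaR1 response regulators
    category: interaction
    module_genes: [K07782, K18098]
  - trait_id: secretion_sec_srp       # Sec-SRP general secretion pathway
    category: interaction
    module_genes: [K03070, K03072, K03073, K03074, K03076, K03106, K03110, K03210, K03217]
  - trait_id: pilus_adhesion          # type IV pilus assembly / adhesion
    category: interaction
    module_genes: [K02650, K02652, K02653, K02658, K02662, K02666, K02669]
  - trait_id: flagellar_motility      # flagellar assembly and motor
    category: interaction
    module_genes: [K02406, K02387, K02388, K02400, K02556, K02557]
  - trait_id: metal_efflux            # heavy-metal efflux / detoxification
    category: interaction
    module_genes: [K07787, K15726, K01534, K03893, K00520]
  - trait_id: metal_storage           # bacterioferritin / Dps iron-storage
    category: interaction
    module_genes: [K03594, K04047]
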