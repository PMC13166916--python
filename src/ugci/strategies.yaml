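# Management-strategy lookup: land-cover class -> limited component(s) -> text.
# Keys under each class: single component names, "all" (uniformly low /
# center of the ternary plot), and "general" (no single dominant limitation).
# Edit freely; wording is advisory and meant to be localized.
forest:
  vegetation_c: >-
    Promote natural regeneration and enrichment planting of native canopy
    species; protect existing stands from clearing and excessive thinning.
  soil_c: >-
    Avoid intensive leaf-litter removal, retain deadwood, and establish
    shade-tolerant native understory shrubs and groundcovers to limit soil
    exposure and conserve soil moisture, especially in edge zones.
  net_uptake: >-
    Favour vigorous mixed-age stand structure; relieve stressors (soil
    compaction on trails, pollutant inputs) that suppress canopy
    photosynthesis.
  soil_potential: >-
    Where feasible amend coarse-textured fill with fine mineral material and
    stabilized organic matter to build mineral-associated carbon capacity.
  all: >-
    Bundle edge-focused measures: understory establishment, litter and
    deadwood retention, and protection from encroachment and disturbance.
  general: >-
    Maintain canopy continuity and minimize disturbance; prioritize edge
    buffers over interior intervention.
park:
  vegetation_c: >-
    Increase planting density with multilayered native tree and shrub
    arrangements; convert amenity lawn margins to woody vegetation where use
    allows.
  soil_c: >-
    Alleviate compaction through periodic aeration combined with organic
    mulch or compost amendments; preserve litter layers; plant deep-rooted
    shrub species.
  net_uptake: >-
    Improve growing conditions (irrigation during drought, soil
    decompaction) so younger park trees approach their photosynthetic
    potential.
  soil_potential: >-
    Specify loam-rich soil mixes in renovations instead of sand-dominated
    fill; amend existing beds with fine-textured material.
  all: >-
    Combine aeration and organic amendments with multilayered plantings, and
    link parks through green corridors and pocket-park stepping stones.
  general: >-
    Balance recreational use with densified planting and soil care in
    low-scoring sections.
agricultural:
  vegetation_c: >-
    Integrate woody elements (hedgerows, agroforestry strips) and
    winter cover crops to keep living biomass on the land year-round.
  soil_c: >-
    Adopt conservation agriculture: retain crop residues as surface mulch,
    reduce tillage intensity toward no-till or strip-till, and apply biochar
    or compost to build soil carbon.
  net_uptake: >-
    Extend the period of active photosynthesis with cover crops and reduced
    fallow; avoid burning residues.
  soil_potential: >-
    Minimize topsoil loss; maintain texture by preventing erosion and
    avoiding subsoil admixture during land forming.
  all: >-
    Apply the conservation-agriculture bundle (residue retention, reduced
    tillage, organic amendments) together with field-margin woody planting.
  general: >-
    Reduce disturbance frequency and keep the soil covered between cropping
    cycles.
roadside:
  vegetation_c: >-
    Design multilayered roadside plantings with drought-tolerant understory
    species; apply pruning regimes that maintain canopy vigour while
    avoiding excessive biomass removal.
  soil_c: >-
    Mitigate soil sealing and compaction by enlarging planting strips and
    using permeable surfaces; retain litter and apply organic mulch within
    tree pits.
  net_uptake: >-
    Relieve heat and drought stress (larger rooting volumes, water-retentive
    substrates, summer irrigation) so street trees remain net carbon sinks.
  soil_potential: >-
    Replace or amend coarse sand-dominated construction fill in planting
    strips with finer-textured engineered soils.
  all: >-
    Integrate the full package: multilayer drought-tolerant planting,
    enlarged permeable planting strips, decompaction, and engineered soil
    amendment.
  general: >-
    Prioritize rooting-space and substrate improvements alongside canopy
    maintenance.
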