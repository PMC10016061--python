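# Bilateral subnetwork definitions used by the volumetric asymmetry index.
# Each entry lists AAL base names (hemisphere suffix stripped); a region is
# included in both its _L and _R form.
#
# The subcortical set is the conventional AAL subcortical grouping; it is an
# interpretation, since published descriptions of "a subcortical network"
# rarely enumerate members.
language:
  - Frontal_Inf_Oper
  - Frontal_Inf_Tri
  - Frontal_Inf_Orb
  - Rolandic_Oper
  - Temporal_Sup
  - Temporal_Pole_Sup
  - Temporal_Mid
  - Temporal_Pole_Mid
  - Postcentral
  - Parietal_Sup
  - Parietal_Inf
  - SupraMarginal
  - Angular
subcortical:
  - Hippocampus
  - Amygdala
  - Caudate
  - Putamen
  - Pallidum
  - Thalamus
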