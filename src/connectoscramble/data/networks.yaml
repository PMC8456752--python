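# A-priori 10-node networks on the AAL-116 parcellation.
#
# Each network is a list of exactly 10 AAL region labels (see aal116.tsv).
# The region families are the standard descriptions of the default mode,
# central executive and salience networks; which lateralized AAL areas fill
# each family to exactly 10 nodes is a package choice and can be overridden
# by passing your own YAML file of the same shape.
DMN:
  - Frontal_Med_Orb_L
  - Frontal_Med_Orb_R
  - Cingulum_Post_L
  - Cingulum_Post_R
  - ParaHippocampal_L
  - ParaHippocampal_R
  - Precuneus_L
  - Precuneus_R
  - Parietal_Inf_L
  - Parietal_Inf_R
CEN:
  - Frontal_Mid_L
  - Frontal_Mid_R
  - Frontal_Inf_Tri_L
  - Frontal_Inf_Tri_R
  - Frontal_Sup_Medial_L
  - Frontal_Sup_Medial_R
  - Parietal_Sup_L
  - Parietal_Sup_R
  - Parietal_Inf_L
  - Parietal_Inf_R
SAL:
  - Insula_L
  - Insula_R
  - Cingulum_Ant_L
  - Cingulum_Ant_R
  - Amygdala_L
  - Amygdala_R
  - Temporal_Pole_Mid_L
  - Temporal_Pole_Mid_R
  - Temporal_Pole_Sup_L
  - Temporal_Pole_Sup_R
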