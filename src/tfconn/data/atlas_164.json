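{
 "name": "atlas-164",
 "networks": {
  "DefaultMode": [
   "MPFC",
   "LP (L)",
   "LP (R)",
   "PCC"
  ],
  "SensoriMotor": [
   "Lateral (L)",
   "Lateral (R)",
   "Superior"
  ],
  "Visual": [
   "Medial",
   "Occipital",
   "Lateral (L)",
   "Lateral (R)"
  ],
  "Salience": [
   "ACC",
   "AInsula (L)",
   "AInsula (R)",
   "RPFC (L)",
   "RPFC (R)",
   "SMG (L)",
   "SMG (R)"
  ],
  "DorsalAttention": [
   "FEF (L)",
   "FEF (R)",
   "IPS (L)",
   "IPS (R)"
  ],
  "FrontoParietal": [
   "LPFC (L)",
   "LPFC (R)",
   "PPC (L)",
   "PPC (R)"
  ],
  "Language": [
   "IFG (L)",
   "IFG (R)",
   "pSTG (L)",
   "pSTG (R)"
  ],
  "Cerebellar": [
   "Anterior",
   "Posterior"
  ]
 },
 "anatomical": [
  "Frontal Pole (L)",
  "Frontal Pole (R)",
  "Insular Cortex (L)",
  "Insular Cortex (R)",
  "Superior Frontal Gyrus (L)",
  "Superior Frontal Gyrus (R)",
  "Middle Frontal Gyrus (L)",
  "Middle Frontal Gyrus (R)",
  "Inferior Frontal Gyrus, pars triangularis (L)",
  "Inferior Frontal Gyrus, pars triangularis (R)",
  "Inferior Frontal Gyrus, pars opercularis (L)",
  "Inferior Frontal Gyrus, pars opercularis (R)",
  "Precentral Gyrus (L)",
  "Precentral Gyrus (R)",
  "Temporal Pole (L)",
  "Temporal Pole (R)",
  "Superior Temporal Gyrus, anterior division (L)",
  "Superior Temporal Gyrus, anterior division (R)",
  "Superior Temporal Gyrus, posterior division (L)",
  "Superior Temporal Gyrus, posterior division (R)",
  "Middle Temporal Gyrus, anterior division (L)",
  "Middle Temporal Gyrus, anterior division (R)",
  "Middle Temporal Gyrus, posterior division (L)",
  "Middle Temporal Gyrus, posterior division (R)",
  "Middle Temporal Gyrus, temporooccipital part (L)",
  "Middle Temporal Gyrus, temporooccipital part (R)",
  "Inferior Temporal Gyrus, anterior division (L)",
  "Inferior Temporal Gyrus, anterior division (R)",
  "Inferior Temporal Gyrus, posterior division (L)",
  "Inferior Temporal Gyrus, posterior division (R)",
  "Inferior Temporal Gyrus, temporooccipital part (L)",
  "Inferior Temporal Gyrus, temporooccipital part (R)",
  "Postcentral Gyrus (L)",
  "Postcentral Gyrus (R)",
  "Superior Parietal Lobule (L)",
  "Superior Parietal Lobule (R)",
  "Supramarginal Gyrus, anterior division (L)",
  "Supramarginal Gyrus, anterior division (R)",
  "Supramarginal Gyrus, posterior division (L)",
  "Supramarginal Gyrus, posterior division (R)",
  "Angular Gyrus (L)",
  "Angular Gyrus (R)",
  "Lateral Occipital Cortex, superior division (L)",
  "Lateral Occipital Cortex, superior division (R)",
  "Lateral Occipital Cortex, inferior division (L)",
  "Lateral Occipital Cortex, inferior division (R)",
  "Intracalcarine Cortex (L)",
  "Intracalcarine Cortex (R)",
  "Frontal Medial Cortex (L)",
  "Frontal Medial Cortex (R)",
  "Juxtapositional Lobule Cortex (L)",
  "Juxtapositional Lobule Cortex (R)",
  "Subcallosal Cortex (L)",
  "Subcallosal Cortex (R)",
  "Paracingulate Gyrus (L)",
  "Paracingulate Gyrus (R)",
  "Cingulate Gyrus, anterior division (L)",
  "Cingulate Gyrus, anterior division (R)",
  "Cingulate Gyrus, posterior division (L)",
  "Cingulate Gyrus, posterior division (R)",
  "Precuneous Cortex (L)",
  "Precuneous Cortex (R)",
  "Cuneal Cortex (L)",
  "Cuneal Cortex (R)",
  "Frontal Orbital Cortex (L)",
  "Frontal Orbital Cortex (R)",
  "Parahippocampal Gyrus, anterior division (L)",
  "Parahippocampal Gyrus, anterior division (R)",
  "Parahippocampal Gyrus, posterior division (L)",
  "Parahippocampal Gyrus, posterior division (R)",
  "Lingual Gyrus (L)",
  "Lingual Gyrus (R)",
  "Temporal Fusiform Cortex, anterior division (L)",
  "Temporal Fusiform Cortex, anterior division (R)",
  "Temporal Fusiform Cortex, posterior division (L)",
  "Temporal Fusiform Cortex, posterior division (R)",
  "Temporal Occipital Fusiform Cortex (L)",
  "Temporal Occipital Fusiform Cortex (R)",
  "Occipital Fusiform Gyrus (L)",
  "Occipital Fusiform Gyrus (R)",
  "Frontal Operculum Cortex (L)",
  "Frontal Operculum Cortex (R)",
  "Central Opercular Cortex (L)",
  "Central Opercular Cortex (R)",
  "Parietal Operculum Cortex (L)",
  "Parietal Operculum Cortex (R)",
  "Planum Polare (L)",
  "Planum Polare (R)",
  "Heschl's Gyrus (L)",
  "Heschl's Gyrus (R)",
  "Planum Temporale (L)",
  "Planum Temporale (R)",
  "Supracalcarine Cortex (L)",
  "Supracalcarine Cortex (R)",
  "Occipital Pole (L)",
  "Occipital Pole (R)",
  "Thalamus (L)",
  "Thalamus (R)",
  "Caudate (L)",
  "Caudate (R)",
  "Putamen (L)",
  "Putamen (R)",
  "Pallidum (L)",
  "Pallidum (R)",
  "Hippocampus (L)",
  "Hippocampus (R)",
  "Cerebelum Crus I (L)",
  "Cerebelum Crus I (R)",
  "Cerebelum Crus II (L)",
  "Cerebelum Crus II (R)",
  "Cerebelum III (L)",
  "Cerebelum III (R)",
  "Cerebelum IV-V (L)",
  "Cerebelum IV-V (R)",
  "Cerebelum VI (L)",
  "Cerebelum VI (R)",
  "Cerebelum VIIb (L)",
  "Cerebelum VIIb (R)",
  "Cerebelum VIII (L)",
  "Cerebelum VIII (R)",
  "Cerebelum IX (L)",
  "Cerebelum IX (R)",
  "Cerebelum X (L)",
  "Cerebelum X (R)",
  "Vermis 1-2",
  "Vermis 3",
  "Vermis 4-5",
  "Vermis 6",
  "Vermis 7",
  "Vermis 8",
  "Vermis 9",
  "Vermis 10"
 ]
}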