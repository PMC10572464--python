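{
 "name": "networks-8",
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
 }
}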