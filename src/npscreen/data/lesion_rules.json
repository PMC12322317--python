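{
  "version": "1.0",
  "description": "Binarization rules for the 14-lesion neuropathology panel. Each lesion has an ordered raw grade scale and a partition of that scale into low and high grades. A missing raw grade binarizes to neither.",
  "lesions": [
    {"code": "ADNC", "name": "Alzheimer's disease neuropathologic change", "domain": "amyloid",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "BRAAK", "name": "Braak stage", "domain": "amyloid",
     "scale": ["none", "I", "II", "III", "IV", "V", "VI"],
     "low": ["none", "I", "II"], "high": ["III", "IV", "V", "VI"]},
    {"code": "DIFF", "name": "Density of diffuse plaques", "domain": "amyloid",
     "scale": ["none", "sparse", "intermediate", "frequent"],
     "low": ["none", "sparse"], "high": ["intermediate", "frequent"]},
    {"code": "NEUR", "name": "Density of neocortical neuritic plaques", "domain": "amyloid",
     "scale": ["none", "sparse", "intermediate", "frequent"],
     "low": ["none", "sparse"], "high": ["intermediate", "frequent"]},
    {"code": "CAA", "name": "Cerebral amyloid angiopathy", "domain": "amyloid",
     "scale": ["none", "mild", "moderate", "severe"],
     "low": ["none", "mild"], "high": ["moderate", "severe"]},
    {"code": "INF", "name": "Infarcts", "domain": "cerebrovascular",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "MICR", "name": "Microinfarcts", "domain": "cerebrovascular",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "HEM", "name": "Hemorrhages and microbleeds", "domain": "cerebrovascular",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "ARTE", "name": "Arteriolosclerosis", "domain": "cerebrovascular",
     "scale": ["none", "mild", "moderate", "severe"],
     "low": ["none", "mild"], "high": ["moderate", "severe"]},
    {"code": "AVAS", "name": "Atherosclerosis of the circle of Willis", "domain": "cerebrovascular",
     "scale": ["none", "mild", "moderate", "severe"],
     "low": ["none", "mild"], "high": ["moderate", "severe"]},
    {"code": "WMR", "name": "White matter rarefaction", "domain": "cerebrovascular",
     "scale": ["none", "mild", "moderate", "severe"],
     "low": ["none", "mild"], "high": ["moderate", "severe"]},
    {"code": "LEWY", "name": "Lewy body disease", "domain": "other",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "SCL", "name": "Hippocampal and/or medial temporal lobe sclerosis", "domain": "other",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]},
    {"code": "TDP", "name": "pTDP-43 across 5 regions", "domain": "other",
     "scale": ["absent", "present"], "low": ["absent"], "high": ["present"]}
  ]
}
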