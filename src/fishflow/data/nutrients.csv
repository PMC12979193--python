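name,category,content,content_unit,requirement,requirement_unit,requirement_basis,requirement_per_kg_mg
Protein,macronutrient,80.6,g,48,g,per-kg-bodyweight,830
Total lipids,macronutrient,12.5,g,,,energy-percent,
EPA+DHA,macronutrient,1.6,g,250,mg,absolute,
Lysine,essential amino acid,6.4,g,1.74,g,per-kg-bodyweight,30
Histidine,essential amino acid,2.8,g,0.58,g,per-kg-bodyweight,10
Isoleucine,essential amino acid,3.8,g,1.16,g,per-kg-bodyweight,20
Leucine,essential amino acid,5.9,g,2.26,g,per-kg-bodyweight,39
Methionine,essential amino acid,2.6,g,0.87,g,per-kg-bodyweight,15
Phenylalanine,essential amino acid,3.3,g,1.45,g,per-kg-bodyweight,25
Threonine,essential amino acid,3.5,g,0.87,g,per-kg-bodyweight,15
Tryptophan,essential amino acid,1.0,g,0.23,g,per-kg-bodyweight,4
Valine,essential amino acid,3.9,g,1.51,g,per-kg-bodyweight,26
Selenium,mineral,23.4,ug,26,ug,absolute,
Calcium,mineral,29.3,mg,1000,mg,absolute,
Magnesium,mineral,19.8,mg,310,mg,absolute,
Vitamin D,vitamin,5.0,ug,15,ug,absolute,
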