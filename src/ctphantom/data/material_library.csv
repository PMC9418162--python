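name,material_class,tissue,hu_ref,delta_70,delta_80,delta_100,delta_140,underfillable,polymer,product,notes
Vinyl,filament,bone,996,324,214,84,-38,True,Polyvinyl chloride,Vinyl 303 natural; Fillamentum Manufacturing Czech s.r.o.,
PLA/stone,filament,bone,1063,12,15,8,8,True,PLA with 50% powdered stone,StoneFil Pottery Clay; Formfutura BV,
PLA/chalk,filament,bone,537,-59,-35,-11,13,True,Polylactic acid (PLA) with chalk powder,PLA Mineral natural; Fiberlogy SA,
PLA-PHA/glow,filament,bone,353,-43,-23,-6,8,True,PLA/Polyhydroxyalkanoate (PHA) with phosphorescent pigment,GlowFill; colorFabb BV,
HIPS,filament,fat,-42,-15,-8,-3,3,True,High impact polystyrene,HIPS wonderous white; ICE Filaments,
PP,filament,fat,-140,,,,,True,Polypropylene,PP; Verbatim GmbH,
ABS,filament,,,,,,,True,Acrylonitrile butadiene styrene,ABS transparent; Verbatim GmbH,
ASA,filament,,,,,,,True,Acrylonitrile styrene acrylate,ASA Extrafill natural; Fillamentum Manufacturing Czech s.r.o.,
Nylon,filament,,,,,,,True,Polyamide,Nylon transparent; Ultimaker BV,
TPU,filament,,,,,,,True,Thermoplastic polyurethane,TPU transparent; Extrudr FD3D GmbH,underfilling not advised (difficult to print)
FL elastic,resin,,,,,,,False,Photocured elastic resin,Formlabs Elastic Resin; Formlabs Inc.,
FL flex,resin,,,,,,,False,Photocured flexible resin,Formlabs Flexible Resin; Formlabs Inc.,
Tango,resin,,,,,,,False,Photocured flexible resin,Tango Plus translucent; Stratasys Ltd.,
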