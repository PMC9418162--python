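target_label,target_hu,tissue_class,material,filling_percent,delta_70,delta_80,delta_100,delta_140
Soft bone,350,bone,PLA/stone,65.4,176,118,43,-22
Soft bone,350,bone,PLA/chalk,87.8,7,7,4,2
Average whole bone,500,bone,PLA/stone,72.7,142,96,35,-16
Average whole bone,500,bone,PLA/chalk,97.6,-46,-27,-8,11
Dense/cortical bone,1000,bone,PLA/stone,96.9,27,24,11,6
Adipose tissue,-80,adipose,Nylon,84.1,-1,2,1,1
Adipose tissue,-80,adipose,ABS,89.3,-4,0,1,2
Adipose tissue,-80,adipose,ASA,91.8,-6,-2,0,1
Adipose tissue,-80,adipose,HIPS,96.0,-13,-6,-2,3
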