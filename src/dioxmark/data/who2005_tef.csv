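congener_id,compound_class,n_chlorines,tef
2378-TeCDD,PCDD,4,1.0
12378-PeCDD,PCDD,5,1.0
123478-HxCDD,PCDD,6,0.1
123678-HxCDD,PCDD,6,0.1
123789-HxCDD,PCDD,6,0.1
1234678-HpCDD,PCDD,7,0.01
OCDD,PCDD,8,0.0003
2378-TeCDF,PCDF,4,0.1
12378-PeCDF,PCDF,5,0.03
23478-PeCDF,PCDF,5,0.3
123478-HxCDF,PCDF,6,0.1
123678-HxCDF,PCDF,6,0.1
123789-HxCDF,PCDF,6,0.1
234678-HxCDF,PCDF,6,0.1
1234678-HpCDF,PCDF,7,0.01
1234789-HpCDF,PCDF,7,0.01
OCDF,PCDF,8,0.0003
PCB77,dlPCB,4,0.0001
PCB81,dlPCB,4,0.0003
PCB105,dlPCB,5,0.00003
PCB114,dlPCB,5,0.00003
PCB118,dlPCB,5,0.00003
PCB123,dlPCB,5,0.00003
PCB126,dlPCB,5,0.1
PCB156,dlPCB,6,0.00003
PCB157,dlPCB,6,0.00003
PCB167,dlPCB,6,0.00003
PCB169,dlPCB,6,0.03
PCB189,dlPCB,7,0.00003
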