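(AQUE,NVEC,HVUL,TADH,MLEI,HSAP,BFLO,SPUR,(DMEL,TCAS,CELE,PTEP,(CTEL,HROB,LANA,SMED,(ACHI,HSCH,(OBIM,NPOM,(LGIG,BGLA,ACAL,HRUF,PCAN,(CGIG,PFUC,MGAL,PYES,SGLO,DRERO)Bivalvia)Bivalvia_Gastropoda)Conchifera)Mollusca)Lophotrochozoa)Protostomia)Metazoa;
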