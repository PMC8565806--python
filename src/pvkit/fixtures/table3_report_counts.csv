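generation,drug,n
1st,Ceftezole,2325
1st,Cefathiamidine,815
1st,Cefazolin pentahydrate,240
1st,Cefazolin,169
1st,Cefazedone,65
1st,Cefadroxil,37
1st,Cefalexin,17
1st,Cefradine,16
1st,Cefalotin,2
1st,Cefalexin/Trimethoprim,1
2nd,Cefamandole nafate,1589
2nd,Cefuroxime,1394
2nd,Cefotiam,231
2nd,Cefaclor,150
2nd,Cefprozil,23
2nd,Cefuroxime axetil,14
2nd,Cefonicid,3
3rd,Ceftazidime,1692
3rd,Cefoperazone/Sulbactam,1565
3rd,Cefotaxime,1328
3rd,Ceftriaxone,1128
3rd,Cefoperazone/Tazobactam,924
3rd,Ceftizoxime,700
3rd,Ceftriaxone/Tazobactam,425
3rd,Cefotaxime/Sulbactam,314
3rd,Cefixime,253
3rd,Cefmenoxime,97
3rd,Cefodizime,93
3rd,Cefoperazone,56
3rd,Cefpiramide,56
3rd,Cefdinir,55
3rd,Cefpodoxime proxetil,6
3rd,Ceftazidime/Tazobactam,4
3rd,Ceftriaxone/Sulbactam,1
3rd,Ceftizoxime/Sulbactam,1
4th,Cefepime,64
4th,Cefoselis,1
unknown,Unknown,3
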