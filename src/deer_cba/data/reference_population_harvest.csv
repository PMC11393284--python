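quantity,class,strategy,value,verified
population,FC,1,206,True
population,FC,2,116,True
population,FC,3,295,False
population,FC,4A,202,True
population,FC,4B,190,True
population,FY,1,134,True
population,FY,2,75,True
population,FY,3,83,False
population,FY,4A,101,True
population,FY,4B,95,True
population,FA,1,532,True
population,FA,2,299,True
population,FA,3,677,False
population,FA,4A,510,True
population,FA,4B,480,True
population,MC,1,206,True
population,MC,2,116,True
population,MC,3,295,False
population,MC,4A,202,True
population,MC,4B,190,True
population,MY,1,134,True
population,MY,2,75,True
population,MY,3,83,False
population,MY,4A,101,True
population,MY,4B,95,True
population,YS,1,172,True
population,YS,2,217,True
population,YS,3,56,False
population,YS,4A,171,True
population,YS,4B,185,True
population,NS,1,25,True
population,NS,2,204,True
population,NS,3,53,False
population,NS,4A,69,True
population,NS,4B,95,True
population,MS,1,4,True
population,MS,2,130,True
population,MS,3,50,False
population,MS,4A,47,True
population,MS,4B,50,True
harvest,FC,1,69,False
harvest,FC,2,39,False
harvest,FC,3,208,False
harvest,FC,4A,93,False
harvest,FC,4B,87,False
harvest,FY,1,25,False
harvest,FY,2,14,False
harvest,FY,3,7,False
harvest,FY,4A,16,False
harvest,FY,4B,15,False
harvest,FA,1,100,False
harvest,FA,2,55,False
harvest,FA,3,66,False
harvest,FA,4A,82,False
harvest,FA,4B,77,False
harvest,MC,1,69,False
harvest,MC,2,39,False
harvest,MC,3,208,False
harvest,MC,4A,93,False
harvest,MC,4B,87,False
harvest,MY,1,45,False
harvest,MY,2,0,False
harvest,MY,3,63,False
harvest,MY,4A,26,False
harvest,MY,4B,19,False
harvest,YS,1,70,False
harvest,YS,2,1,False
harvest,YS,3,0,False
harvest,YS,4A,44,False
harvest,YS,4B,36,False
harvest,NS,1,12,False
harvest,NS,2,1,False
harvest,NS,3,0,False
harvest,NS,4A,18,False
harvest,NS,4B,19,False
harvest,MS,1,2,False
harvest,MS,2,63,False
harvest,MS,3,16,False
harvest,MS,4A,12,False
harvest,MS,4B,20,False
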