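set_id,k1,k2,k3,Km1,Km2,Km3,Km4,Km5,n1,n2,n3,a1,a2,a3,flux_ratio,Vmax1,Vmax2,Vmax3,Vmax4,Vmax5,Vmax6
oscillating_1,3.9981553242580565,0.20990258976561604,0.90088936100268,0.9635094995039463,9.527205865634903,0.1492092282970234,1.050836844862445,6.7410288692013465,1.738325789711124,1.4373741838138274,2.1612514843070083,1.5585201149809416,3.615407500286953,1.1247446758558777,0.025853152838957404,407.2631516684235,221.1419549416469,18.6256287064309,76.6139485531349,187.18475158624022,11113.637277983955
oscillating_2,0.12476793501612246,2.510446831126898,0.27882825806165046,5.816128176763899,0.26545032859554174,0.3903727061108613,0.18813174709182512,0.4028448751013857,2.300441884065165,1.448562206887307,1.0694838743533348,2.2542635836208222,2.7699460996908445,1.1629941797066747,0.070248448100045,260.93620161364476,5929.894654019699,6.3741703576523046,92.69151374072409,85.57654956536877,191.49753437005907
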